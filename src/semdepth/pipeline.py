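"""End-to-end orchestration: features -> group tests -> thickness analyses.

``run_full`` produces the three report tables the analysis is organized
around — the per-feature clinical group comparison, the region-wise
thickness contrasts of each clinical group against controls, and the
SDI-thickness correlations over the semantic-network ROIs — plus a run
manifest with input checksums and the configuration echo, so identical
inputs and configuration yield byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .features import (
    FEATURE_COLUMNS,
    FrequencyLexicon,
    extract_features,
    profile_table,
)
from .neuro import correlate_sdi_thickness, group_thickness_contrast, read_thickness
from .stats import mann_whitney_u
from .taxonomy import coverage_report, load_taxonomy
from .transcripts import OPEN_WORD_CLASSES, merge_speaker, read_transcripts

__all__ = ["RunConfig", "run_features", "run_full", "group_comparison"]

CLINICAL_GROUPS = ("svPPA", "lvPPA")


@dataclass
class RunConfig:
    taxonomy: str | Path
    transcripts: str | Path
    frequency: str | Path | None = None
    thickness: str | Path | None = None
    policy: str = "first_sense"
    sdi_weighting: str = "type"
    q: float = 0.05
    outdir: str | Path = "semdepth_out"

    def __post_init__(self) -> None:
        if not 0 < self.q < 1:
            raise ValueError("FDR level q must lie in (0, 1)")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def group_comparison(
    table: pd.DataFrame, group_a: str = "svPPA", group_b: str = "lvPPA"
) -> pd.DataFrame:
    """Feature-wise Mann-Whitney comparison of two groups from a profile
    table: one row per feature with group means/SDs, U and two-sided p."""
    a = table[table["group"] == group_a]
    b = table[table["group"] == group_b]
    if a.empty or b.empty:
        raise ValueError(f"need speakers in both {group_a!r} and {group_b!r}")
    rows = []
    for feat in FEATURE_COLUMNS:
        xa = a[feat].astype(float).dropna().to_numpy()
        xb = b[feat].astype(float).dropna().to_numpy()
        if xa.size == 0 or xb.size == 0:  # feature unavailable (e.g. no lexicon)
            rows.append(
                {
                    "feature": feat,
                    f"mean_{group_a}": math.nan, f"sd_{group_a}": math.nan,
                    f"mean_{group_b}": math.nan, f"sd_{group_b}": math.nan,
                    "u": math.nan, "p": math.nan, "method": "not_available",
                }
            )
            continue
        res = mann_whitney_u(xa, xb)
        rows.append(
            {
                "feature": feat,
                f"mean_{group_a}": xa.mean(),
                f"sd_{group_a}": xa.std(ddof=1) if xa.size > 1 else math.nan,
                f"mean_{group_b}": xb.mean(),
                f"sd_{group_b}": xb.std(ddof=1) if xb.size > 1 else math.nan,
                "u": res.u_reported,
                "p": res.p_two_sided,
                "method": res.method,
            }
        )
    return pd.DataFrame(rows)


def run_features(cfg: RunConfig) -> dict:
    """Per-speaker feature extraction stage.

    Returns profiles, the feature matrix, the coverage report and the
    output paths; writes features.tsv and coverage.json under the output
    directory.
    """
    tax = load_taxonomy(cfg.taxonomy)
    transcripts = read_transcripts(cfg.transcripts)
    lex = FrequencyLexicon.read(cfg.frequency) if cfg.frequency else None

    speakers: list[str] = []
    for t in transcripts:
        if t.speaker_id not in speakers:
            speakers.append(t.speaker_id)
    profiles = []
    all_lemmas: set[tuple[str, str]] = set()
    for sp in speakers:
        mine = [t for t in transcripts if t.speaker_id == sp]
        merged = merge_speaker(mine, sp)
        profiles.append(
            extract_features(merged, tax, lex, policy=cfg.policy,
                             sdi_weighting=cfg.sdi_weighting)
        )
        all_lemmas.update(
            (tok.lemma, tok.word_class)
            for tok in merged.tokens
            if not tok.excluded and tok.word_class in OPEN_WORD_CLASSES
        )
    coverage = coverage_report(tax, sorted(all_lemmas))

    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = profile_table(profiles)
    _write_tsv(table, outdir / "features.tsv")
    cov_echo = {
        "n_distinct_open_lemmas": coverage["n"],
        "found": coverage["found"],
        "coverage": coverage["coverage"],
        "per_pos": coverage["per_pos"],
        "missing": [list(m) for m in coverage["missing"]],
        "policy": cfg.policy,
        "sdi_weighting": cfg.sdi_weighting,
        "taxonomy_metadata": tax.metadata,
    }
    (outdir / "coverage.json").write_text(
        json.dumps(cov_echo, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return {
        "profiles": profiles,
        "table": table,
        "coverage": coverage,
        "outdir": outdir,
    }


def run_full(cfg: RunConfig) -> dict:
    """Full report bundle: feature comparison, thickness contrasts per
    clinical group, semantic-network SDI correlations, and a manifest."""
    if cfg.thickness is None:
        raise ValueError("run_full requires a thickness table")
    stage = run_features(cfg)
    profiles, table, outdir = stage["profiles"], stage["table"], stage["outdir"]

    groups = set(table["group"])
    if len(groups & set(CLINICAL_GROUPS)) < 2:
        raise ValueError("need both clinical groups among the transcripts")
    comparison = group_comparison(table)
    _write_tsv(comparison, outdir / "group_comparison.tsv")

    tt = read_thickness(cfg.thickness)
    tgroups = set(tt.data["group"])
    contrasts = {}
    for g in CLINICAL_GROUPS:
        if g in tgroups and "HC" in tgroups:
            contrasts[g] = group_thickness_contrast(tt, g, "HC")
            _write_tsv(contrasts[g], outdir / f"thickness_contrast_{g}.tsv")

    clinical_profiles = [p for p in profiles if p.group in CLINICAL_GROUPS]
    correlations = correlate_sdi_thickness(
        clinical_profiles, tt, alpha=cfg.q
    )
    _write_tsv(correlations, outdir / "sdi_thickness_correlations.tsv")

    manifest = {
        "version": __version__,
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in (
                ("taxonomy", cfg.taxonomy),
                ("transcripts", cfg.transcripts),
                ("frequency", cfg.frequency),
                ("thickness", cfg.thickness),
            )
            if p is not None
        },
        "config": {
            "policy": cfg.policy,
            "sdi_weighting": cfg.sdi_weighting,
            "q": cfg.q,
        },
        "outputs": sorted(
            p.name for p in outdir.iterdir() if p.suffix in (".tsv", ".json")
            and p.name != "manifest.json"
        ),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return {
        "profiles": profiles,
        "table": table,
        "comparison": comparison,
        "contrasts": contrasts,
        "correlations": correlations,
        "manifest": manifest,
        "outdir": outdir,
    }
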