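"""Regional cortical-thickness tables, semantic-network ROIs, and the
thickness analyses: clinical-vs-control contrasts and SDI correlations.

Thickness arrives as FreeSurfer aparc-stats-style tables over the Desikan
gyral parcellation (34 regions x 2 hemispheres, mm).  Two dialects are
read: wide (one row per subject, columns ``<region>_<lh|rh>_thickness``)
and long (``subject<TAB>group<TAB>region<TAB>hemi<TAB>thickness_mm``).

The a-priori semantic-network family comprises 14 bilateral regions
associated with conceptual processing (the "anterior temporal lobe" entry
maps to the Desikan temporal pole label; the inferior frontal gyrus to its
pars opercularis subdivision).  Group contrasts use Mann-Whitney tests
BH-adjusted within the 68-region family; SDI correlations are Pearson r
over the pooled clinical sample, BH-adjusted within the 28 ROI tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .features import FeatureProfile
from .stats import bh_fdr, mann_whitney_u, pearson_r

__all__ = [
    "DESIKAN_REGIONS",
    "REGION_ORDER",
    "HEMISPHERES",
    "SEMANTIC_NETWORK_ROIS",
    "ThicknessTable",
    "ThicknessError",
    "read_thickness",
    "write_thickness",
    "group_thickness_contrast",
    "correlate_sdi_thickness",
]

HEMISPHERES = ("left", "right")
_HEMI_CODE = {"left": "lh", "right": "rh"}
_CODE_HEMI = {v: k for k, v in _HEMI_CODE.items()}

# (lobe, region) in canonical report order: medial then lateral temporal,
# frontal, parietal, occipital, insula, cingulate; regions alphabetical
# within lobe.  Region names are the FreeSurfer aparc labels.
REGION_ORDER: tuple[tuple[str, str], ...] = (
    ("temporal-medial", "entorhinal"),
    ("temporal-medial", "fusiform"),
    ("temporal-medial", "parahippocampal"),
    ("temporal-medial", "temporalpole"),
    ("temporal-lateral", "bankssts"),
    ("temporal-lateral", "inferiortemporal"),
    ("temporal-lateral", "middletemporal"),
    ("temporal-lateral", "superiortemporal"),
    ("temporal-lateral", "transversetemporal"),
    ("frontal", "caudalmiddlefrontal"),
    ("frontal", "frontalpole"),
    ("frontal", "lateralorbitofrontal"),
    ("frontal", "medialorbitofrontal"),
    ("frontal", "paracentral"),
    ("frontal", "parsopercularis"),
    ("frontal", "parsorbitalis"),
    ("frontal", "parstriangularis"),
    ("frontal", "precentral"),
    ("frontal", "rostralmiddlefrontal"),
    ("frontal", "superiorfrontal"),
    ("parietal", "inferiorparietal"),
    ("parietal", "postcentral"),
    ("parietal", "precuneus"),
    ("parietal", "superiorparietal"),
    ("parietal", "supramarginal"),
    ("occipital", "cuneus"),
    ("occipital", "lateraloccipital"),
    ("occipital", "lingual"),
    ("occipital", "pericalcarine"),
    ("insula", "insula"),
    ("cingulate", "caudalanteriorcingulate"),
    ("cingulate", "isthmuscingulate"),
    ("cingulate", "posteriorcingulate"),
    ("cingulate", "rostralanteriorcingulate"),
)

DESIKAN_REGIONS: tuple[str, ...] = tuple(r for _, r in REGION_ORDER)
_LOBE_OF = {r: lobe for lobe, r in REGION_ORDER}

# 14 a-priori semantic-network regions x both hemispheres (28 tests)
_SEMANTIC_REGIONS = (
    "temporalpole",        # anterior temporal lobe
    "superiortemporal",
    "middletemporal",
    "inferiortemporal",
    "fusiform",
    "parahippocampal",
    "entorhinal",
    "parsopercularis",     # inferior frontal gyrus
    "caudalmiddlefrontal",
    "superiorfrontal",
    "precuneus",
    "supramarginal",
    "posteriorcingulate",
    "rostralanteriorcingulate",
)
SEMANTIC_NETWORK_ROIS: tuple[tuple[str, str], ...] = tuple(
    (region, hemi) for region in _SEMANTIC_REGIONS for hemi in HEMISPHERES
)


class ThicknessError(ValueError):
    pass


@dataclass
class ThicknessTable:
    """Subject x (region, hemisphere) thickness in mm, Desikan labels.

    ``data`` is a long-format frame with columns subject, group, region,
    hemi, thickness_mm.  Values outside the (0, 6) mm physiological band
    raise a QC warning at construction, not an error.
    """

    data: pd.DataFrame
    atlas: str = "desikan"

    def __post_init__(self) -> None:
        required = ["subject", "group", "region", "hemi", "thickness_mm"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ThicknessError(f"missing columns: {missing}")
        bad_region = set(self.data["region"]) - set(DESIKAN_REGIONS)
        if bad_region:
            raise ThicknessError(
                f"unknown atlas label(s): {sorted(bad_region)}"
            )
        bad_hemi = set(self.data["hemi"]) - set(HEMISPHERES)
        if bad_hemi:
            raise ThicknessError(f"unknown hemisphere(s): {sorted(bad_hemi)}")
        th = self.data["thickness_mm"].to_numpy(dtype=float)
        if np.any((th <= 0) | (th >= 6)):
            warnings.warn(
                "thickness value(s) outside the physiological (0, 6) mm band",
                stacklevel=2,
            )

    @property
    def subjects(self) -> list[tuple[str, str]]:
        sub = self.data[["subject", "group"]].drop_duplicates()
        return list(sub.itertuples(index=False, name=None))

    def values_for(
        self, region: str, hemi: str, group: str | None = None
    ) -> pd.Series:
        """Thickness values for one (region, hemi), indexed by subject."""
        d = self.data
        mask = (d["region"] == region) & (d["hemi"] == hemi)
        if group is not None:
            mask &= d["group"] == group
        sel = d.loc[mask]
        return pd.Series(
            sel["thickness_mm"].to_numpy(), index=sel["subject"].to_numpy()
        )


def _parse_wide(df: pd.DataFrame, path: str) -> ThicknessTable:
    records = []
    for col in df.columns:
        if col in ("subject", "group"):
            continue
        parts = col.rsplit("_", 2)
        if len(parts) != 3 or parts[2] != "thickness" or parts[1] not in _CODE_HEMI:
            raise ThicknessError(
                f"{path}: column {col!r} does not match <region>_<lh|rh>_thickness"
            )
        region, code = parts[0], parts[1]
        if region not in DESIKAN_REGIONS:
            raise ThicknessError(f"{path}: unknown atlas label in column {col!r}")
        for _, row in df.iterrows():
            records.append(
                {
                    "subject": str(row["subject"]),
                    "group": str(row["group"]),
                    "region": region,
                    "hemi": _CODE_HEMI[code],
                    "thickness_mm": float(row[col]),
                }
            )
    return ThicknessTable(pd.DataFrame.from_records(records))


def read_thickness(path: str | Path) -> ThicknessTable:
    """Read a wide (aparc-stats style) or long thickness table."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "subject" not in df.columns:
        raise ThicknessError(f"{path}: missing 'subject' column")
    if "thickness_mm" in df.columns:
        for col in ("group", "region", "hemi"):
            if col not in df.columns:
                raise ThicknessError(f"{path}: long format missing {col!r}")
        df = df.astype({"subject": str, "group": str})
        return ThicknessTable(df[["subject", "group", "region", "hemi",
                                  "thickness_mm"]].copy())
    if "group" not in df.columns:
        raise ThicknessError(f"{path}: missing 'group' column")
    return _parse_wide(df, str(path))


def write_thickness(tt: ThicknessTable, path: str | Path) -> None:
    """Write the canonical wide dialect (subjects in first-seen order,
    region columns in atlas order); bit-exact re-readable."""
    cols = [
        f"{region}_{_HEMI_CODE[hemi]}_thickness"
        for region in DESIKAN_REGIONS
        for hemi in HEMISPHERES
    ]
    lookup = {
        (s, r, h): v
        for s, r, h, v in zip(
            tt.data["subject"], tt.data["region"], tt.data["hemi"],
            tt.data["thickness_mm"],
        )
    }
    lines = ["subject\tgroup\t" + "\t".join(cols)]
    for subject, group in tt.subjects:
        vals = []
        for region in DESIKAN_REGIONS:
            for hemi in HEMISPHERES:
                v = lookup.get((subject, region, hemi))
                if v is None:
                    raise ThicknessError(
                        f"subject {subject!r} missing {region}/{hemi}"
                    )
                vals.append(repr(float(v)))
        lines.append(f"{subject}\t{group}\t" + "\t".join(vals))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def group_thickness_contrast(
    tt: ThicknessTable, clinical_group: str, control_group: str = "HC"
) -> pd.DataFrame:
    """Region-wise Mann-Whitney contrast of one clinical group against
    controls, BH-adjusted across the 68 (region, hemisphere) tests.

    Rows come out in canonical atlas order (lobe, region, hemisphere);
    exactly one row per (region, hemisphere), no silent drops.
    """
    groups = set(tt.data["group"])
    for g in (clinical_group, control_group):
        if g not in groups:
            raise ThicknessError(f"group {g!r} absent from thickness table")
    rows = []
    for _, region in REGION_ORDER:
        for hemi in HEMISPHERES:
            x = tt.values_for(region, hemi, clinical_group).to_numpy()
            y = tt.values_for(region, hemi, control_group).to_numpy()
            if x.size < 2 or y.size < 2:
                raise ThicknessError(
                    f"{region}/{hemi}: need >= 2 subjects per group"
                )
            res = mann_whitney_u(x, y)
            rows.append(
                {
                    "lobe": _LOBE_OF[region],
                    "region": region,
                    "hemi": hemi,
                    "n_clinical": res.n1,
                    "n_control": res.n2,
                    "mean_clinical": float(np.mean(x)),
                    "mean_control": float(np.mean(y)),
                    "u": res.u_reported,
                    "p_raw": res.p_two_sided,
                }
            )
    out = pd.DataFrame(rows)
    out["p_fdr"] = bh_fdr(out["p_raw"].to_numpy())
    return out


def correlate_sdi_thickness(
    profiles: Sequence[FeatureProfile],
    tt: ThicknessTable,
    rois: Sequence[tuple[str, str]] = SEMANTIC_NETWORK_ROIS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation of per-speaker mean SDI with ROI thickness over
    the pooled clinical sample, BH-adjusted within the ROI family.

    Every profile's speaker must have thickness values; the output has one
    row per ROI, sorted by raw p with FDR-significant entries flagged.
    """
    sdi = {}
    for p in profiles:
        if p.mean_sdi is None:
            raise ThicknessError(
                f"speaker {p.speaker_id!r} has no mean SDI (no scored words)"
            )
        sdi[p.speaker_id] = float(p.mean_sdi)
    have = set(tt.data["subject"])
    missing = sorted(set(sdi) - have)
    if missing:
        raise ThicknessError(
            f"speaker(s) missing from thickness table: {missing}"
        )
    speakers = list(sdi)
    if len(speakers) < 4:
        raise ThicknessError("need >= 4 subjects for ROI correlations")
    x = np.array([sdi[s] for s in speakers])
    rows = []
    for region, hemi in rois:
        th = tt.values_for(region, hemi)
        y = th.loc[speakers].to_numpy(dtype=float)
        r, p_raw = pearson_r(x, y)
        rows.append(
            {"region": region, "hemi": hemi, "r": r, "p_raw": p_raw,
             "n": len(speakers)}
        )
    out = pd.DataFrame(rows)
    out["p_fdr"] = bh_fdr(out["p_raw"].to_numpy())
    out = out.sort_values("p_raw", kind="stable").reset_index(drop=True)
    out["significant"] = out["p_fdr"] < alpha
    return out
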