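"""Synthetic cohort generator: taxonomy, lexicon, transcripts, thickness.

Real narrative-speech and imaging data for these clinical populations are
not redistributable, so every pipeline input can be simulated with the
statistical structure the analysis assumes:

* a complete b-ary hypernym tree per word class with unique pseudo-word
  lemmas;
* per-speaker transcripts whose open-class lemmas are drawn with
  probability proportional to exp(theta_g * depth) — the one-parameter
  log-linear family in which a lower group weight theta_g produces
  stochastically shallower (more generic) word choices, the hallmark of
  semantic-variant narrative speech;
* paraphasia/filler/event counts drawn as independent Poissons at
  published group rates;
* regional cortical thickness drawn from published per-group normals,
  optionally coupled to each speaker's mean SDI in designated
  semantic-network ROIs.

Group sizes default to 6 svPPA, 16 lvPPA and 30 controls.  All randomness
derives from one master seed through fixed integer stream labels, so a
given seed reproduces byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .features import FeatureProfile, FrequencyLexicon
from .neuro import DESIKAN_REGIONS, HEMISPHERES, ThicknessTable, write_thickness
from .taxonomy import OPEN_CLASSES, Synset, Taxonomy, write_taxonomy
from .transcripts import TASKS, Token, Transcript, Utterance, write_transcripts

import pandas as pd

__all__ = [
    "GROUP_FEATURE_RATES",
    "GROUP_THICKNESS",
    "DEFAULT_LINK_ROIS",
    "CohortConfig",
    "gen_taxonomy",
    "default_taxonomy",
    "calibrate_depth_preference",
    "gen_transcripts",
    "gen_frequency_lexicon",
    "gen_thickness",
    "simulate_cohort",
]

# ---------------------------------------------------------------------------
# Published group-level parameters used as generator defaults.
# Feature table: per-group means of narrative counts (sv/lv from the study
# group tables; HC rates are nominal healthy values — controls contribute no
# published narrative data).
GROUP_FEATURE_RATES: dict[str, dict[str, float]] = {
    "svPPA": {
        "open_tokens_mean": 285.83, "open_tokens_sd": 78.04,
        "closed_tokens_mean": 349.33, "closed_tokens_sd": 120.52,
        "phonemic_paraphasias": 1.50, "semantic_paraphasias": 3.50,
        "anomic_pauses": 6.83, "cda": 6.83,
        "fillers": 12.0, "false_starts": 4.0,
        "well_formed_rate": 0.91, "sdi_target": 3.99,
    },
    "lvPPA": {
        "open_tokens_mean": 161.81, "open_tokens_sd": 55.09,
        "closed_tokens_mean": 271.07, "closed_tokens_sd": 100.95,
        "phonemic_paraphasias": 4.88, "semantic_paraphasias": 2.50,
        "anomic_pauses": 8.63, "cda": 7.19,
        "fillers": 15.0, "false_starts": 6.0,
        "well_formed_rate": 0.62, "sdi_target": 4.42,
    },
    "HC": {
        "open_tokens_mean": 320.0, "open_tokens_sd": 80.0,
        "closed_tokens_mean": 360.0, "closed_tokens_sd": 100.0,
        "phonemic_paraphasias": 0.3, "semantic_paraphasias": 0.3,
        "anomic_pauses": 1.0, "cda": 1.0,
        "fillers": 8.0, "false_starts": 2.0,
        "well_formed_rate": 0.95, "sdi_target": 4.60,
    },
}

# Cortical thickness (mm): (region, hemi) -> per-group (mean, sd) from the
# published Desikan-atlas group table (svPPA, lvPPA, HC columns).
_T3 = """\
entorhinal left 1.77 0.27 2.60 0.51 3.20 0.42
entorhinal right 2.28 0.32 2.83 0.47 3.38 0.40
fusiform left 1.99 0.25 2.18 0.43 2.56 0.11
fusiform right 2.15 0.22 2.30 0.18 2.57 0.11
parahippocampal left 1.88 0.24 2.25 0.46 2.58 0.26
parahippocampal right 2.01 0.30 2.31 0.38 2.51 0.24
temporalpole left 2.34 0.51 3.06 0.59 3.47 0.39
temporalpole right 2.83 0.72 3.17 0.53 3.59 0.35
bankssts left 1.87 0.31 1.98 0.24 2.35 0.17
bankssts right 2.06 0.27 2.12 0.23 2.44 0.16
inferiortemporal left 1.99 0.31 2.30 0.37 2.66 0.19
inferiortemporal right 2.36 0.25 2.43 0.23 2.70 0.17
middletemporal left 2.04 0.33 2.34 0.35 2.70 0.18
middletemporal right 2.28 0.23 2.48 0.22 2.72 0.17
superiortemporal left 1.86 0.26 2.17 0.31 2.57 0.17
superiortemporal right 2.16 0.26 2.34 0.21 2.60 0.19
transversetemporal left 1.97 0.37 1.92 0.34 2.21 0.25
transversetemporal right 2.10 0.46 2.16 0.22 2.26 0.25
caudalmiddlefrontal left 2.14 0.26 2.05 0.25 2.40 0.16
caudalmiddlefrontal right 2.16 0.32 2.18 0.16 2.38 0.12
frontalpole left 2.38 0.23 2.56 0.39 2.72 0.25
frontalpole right 2.53 0.21 2.70 0.23 2.76 0.29
lateralorbitofrontal left 2.27 0.30 2.50 0.34 2.57 0.15
lateralorbitofrontal right 2.38 0.19 2.51 0.22 2.52 0.16
medialorbitofrontal left 2.12 0.20 2.35 0.36 2.40 0.13
medialorbitofrontal right 2.28 0.21 2.45 0.19 2.41 0.19
paracentral left 2.05 0.30 1.96 0.32 2.23 0.25
paracentral right 2.15 0.19 2.03 0.21 2.23 0.23
parsopercularis left 2.22 0.26 2.21 0.24 2.45 0.13
parsopercularis right 2.22 0.29 2.29 0.19 2.46 0.12
parsorbitalis left 2.34 0.35 2.43 0.32 2.54 0.14
parsorbitalis right 2.45 0.18 2.48 0.20 2.52 0.18
parstriangularis left 2.13 0.28 2.12 0.27 2.30 0.13
parstriangularis right 2.18 0.21 2.25 0.16 2.31 0.10
precentral left 2.13 0.30 2.04 0.30 2.38 0.24
precentral right 2.20 0.27 2.11 0.26 2.35 0.23
rostralmiddlefrontal left 2.01 0.25 2.07 0.24 2.27 0.11
rostralmiddlefrontal right 2.09 0.22 2.15 0.13 2.25 0.12
superiorfrontal left 2.29 0.31 2.26 0.28 2.54 0.17
superiorfrontal right 2.33 0.26 2.35 0.14 2.52 0.14
inferiorparietal left 1.93 0.27 1.91 0.28 2.29 0.13
inferiorparietal right 2.09 0.20 2.01 0.20 2.32 0.14
postcentral left 1.78 0.13 1.72 0.17 2.00 0.15
postcentral right 1.81 0.17 1.82 0.13 1.97 0.18
precuneus left 1.95 0.24 1.89 0.26 2.23 0.15
precuneus right 2.00 0.23 1.99 0.19 2.18 0.17
superiorparietal left 1.85 0.22 1.75 0.24 2.08 0.14
superiorparietal right 1.92 0.24 1.84 0.16 2.07 0.16
supramarginal left 2.13 0.24 1.97 0.22 2.38 0.13
supramarginal right 2.21 0.16 2.08 0.12 2.36 0.17
cuneus left 1.62 0.15 1.68 0.18 1.81 0.18
cuneus right 1.64 0.15 1.66 0.13 1.75 0.20
lateraloccipital left 1.94 0.15 1.86 0.21 2.01 0.15
lateraloccipital right 1.97 0.20 1.96 0.14 2.09 0.16
lingual left 1.80 0.13 1.75 0.22 1.91 0.16
lingual right 1.82 0.14 1.81 0.10 1.90 0.16
pericalcarine left 1.54 0.17 1.51 0.17 1.55 0.20
pericalcarine right 1.50 0.17 1.50 0.18 1.57 0.18
insula left 2.51 0.29 2.55 0.37 2.91 0.21
insula right 2.69 0.13 2.68 0.29 2.92 0.20
caudalanteriorcingulate left 2.61 0.19 2.58 0.37 2.68 0.29
caudalanteriorcingulate right 2.53 0.14 2.57 0.28 2.63 0.28
isthmuscingulate left 2.01 0.11 1.97 0.27 2.29 0.24
isthmuscingulate right 2.11 0.13 1.99 0.16 2.26 0.17
posteriorcingulate left 2.09 0.24 2.11 0.34 2.40 0.20
posteriorcingulate right 2.24 0.18 2.19 0.18 2.38 0.19
rostralanteriorcingulate left 2.39 0.32 2.55 0.41 2.80 0.25
rostralanteriorcingulate right 2.62 0.26 2.76 0.25 2.77 0.26
"""

GROUP_THICKNESS: dict[tuple[str, str], dict[str, tuple[float, float]]] = {}
for _line in _T3.strip().splitlines():
    _f = _line.split()
    GROUP_THICKNESS[(_f[0], _f[1])] = {
        "svPPA": (float(_f[2]), float(_f[3])),
        "lvPPA": (float(_f[4]), float(_f[5])),
        "HC": (float(_f[6]), float(_f[7])),
    }
assert len(GROUP_THICKNESS) == 68

# ROIs reported as associated with mean SDI: default targets of the
# planted SDI-thickness coupling.
DEFAULT_LINK_ROIS: tuple[tuple[str, str], ...] = (
    ("entorhinal", "left"),
    ("entorhinal", "right"),
    ("temporalpole", "left"),
    ("temporalpole", "right"),
    ("parahippocampal", "left"),
    ("parahippocampal", "right"),
    ("middletemporal", "left"),
    ("superiortemporal", "left"),
)

# open-token word-class mix (shared across groups; type counts emerge)
CLASS_MIX: dict[str, float] = {
    "noun": 0.40, "verb": 0.38, "adjective": 0.14, "adverb": 0.08,
}

CLOSED_CLASS_LEMMAS = (
    "the a an and or but of in on at to from with by for is are was be "
    "have has not no yes it he she they we you i this that there then so "
    "if because while"
).split()

_FILLERS = ("uh", "um", "eh", "mm")


@dataclass
class CohortConfig:
    """Study-condition parameters of one synthetic cohort.

    ``depth_preference`` maps group -> theta; entries left as None are
    calibrated so the token-level expected depth matches the group's
    ``sdi_target`` (published mean SDI for the clinical groups).

    The thickness link plants the SDI-thickness association in
    ``link_rois``.  ``link_mode="group_anchored"`` (default) preserves each
    group's published thickness mean/SD exactly and couples the
    within-group residual to mean SDI with correlation ``link_r``;
    ``"pooled"`` fits one linear model across the pooled clinical sample
    so the pooled correlation equals ``link_r`` (0 gives exact
    independence) — the mode used for correlation-recovery and null
    calibration experiments.
    """

    seed: int = 0
    n_sv: int = 6
    n_lv: int = 16
    n_hc: int = 30
    depth_preference: dict[str, float | None] = field(
        default_factory=lambda: {"svPPA": None, "lvPPA": None, "HC": None}
    )
    feature_rates: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in GROUP_FEATURE_RATES.items()}
    )
    class_mix: dict[str, float] = field(default_factory=lambda: dict(CLASS_MIX))
    utterance_len: tuple[int, int] = (3, 7)  # uniform inclusive
    link_mode: str = "group_anchored"
    link_rois: tuple[tuple[str, str], ...] = DEFAULT_LINK_ROIS
    link_r: float = 0.4
    thickness: dict[tuple[str, str], dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in GROUP_THICKNESS.items()}
    )

    def __post_init__(self) -> None:
        if min(self.n_sv, self.n_lv) < 0 or self.n_hc < 0:
            raise ValueError("group sizes must be non-negative")
        if self.link_mode not in ("group_anchored", "pooled"):
            raise ValueError(f"unknown link_mode {self.link_mode!r}")
        if not -1.0 <= self.link_r <= 1.0:
            raise ValueError("link_r must lie in [-1, 1]")

    def roster(self) -> list[tuple[str, str]]:
        """(speaker_id, group) pairs, clinical first."""
        out = [(f"sv{i+1:02d}", "svPPA") for i in range(self.n_sv)]
        out += [(f"lv{i+1:02d}", "lvPPA") for i in range(self.n_lv)]
        out += [(f"hc{i+1:02d}", "HC") for i in range(self.n_hc)]
        return out


# ---------------------------------------------------------------------------
# taxonomy + lexicon generation

_CONSONANTS = "bdfgklmnprstvz"
_VOWELS = "aeiou"


def _pseudoword(rng: np.random.Generator, used: set[str]) -> str:
    for _ in range(100):
        n_syll = int(rng.integers(2, 4))
        word = "".join(
            _CONSONANTS[rng.integers(len(_CONSONANTS))]
            + _VOWELS[rng.integers(len(_VOWELS))]
            for _ in range(n_syll)
        )
        if word not in used:
            used.add(word)
            return word
    word = f"{word}{len(used)}"  # fall back to a numbered form
    used.add(word)
    return word


def gen_taxonomy(
    seed: int,
    n_roots: int = 1,
    branching: int = 2,
    max_depth: int = 8,
    pos: str = "noun",
    _used: set[str] | None = None,
) -> Taxonomy:
    """Complete ``branching``-ary hypernym tree(s) of the given word class
    with unique pseudo-word lemmas; deterministic under ``seed``."""
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    if branching < 1 or n_roots < 1:
        raise ValueError("branching and n_roots must be >= 1")
    from .taxonomy import POS_TAGS

    prefix = {"noun": "n", "verb": "v", "adjective": "j", "adverb": "r"}[pos]
    rng = np.random.default_rng([seed, 10, POS_TAGS.index(pos)])
    used = _used if _used is not None else set()
    synsets: list[Synset] = []
    edges: list[tuple[str, str]] = []
    counter = 0
    for _root in range(n_roots):
        frontier: list[str] = []
        sid = f"{prefix}{counter:05d}"
        counter += 1
        synsets.append(Synset(id=sid, pos=pos, lemmas=(_pseudoword(rng, used),)))
        frontier.append(sid)
        for _depth in range(max_depth):
            nxt: list[str] = []
            for parent in frontier:
                for _ in range(branching):
                    sid = f"{prefix}{counter:05d}"
                    counter += 1
                    synsets.append(
                        Synset(id=sid, pos=pos, lemmas=(_pseudoword(rng, used),))
                    )
                    edges.append((sid, parent))
                    nxt.append(sid)
            frontier = nxt
    return Taxonomy(synsets, edges, metadata={"generator": f"synthetic-{pos}"})


def default_taxonomy(seed: int) -> Taxonomy:
    """Default four-class taxonomy: binary trees of depth 8 (nouns),
    6 (verbs), 5 (adjectives) and 4 (adverbs)."""
    used: set[str] = set()
    parts = [
        gen_taxonomy(seed, 1, 2, 8, "noun", _used=used),
        gen_taxonomy(seed, 1, 2, 6, "verb", _used=used),
        gen_taxonomy(seed, 1, 2, 5, "adjective", _used=used),
        gen_taxonomy(seed, 1, 2, 4, "adverb", _used=used),
    ]
    synsets = [s for t in parts for s in t.synsets.values()]
    edges = [e for t in parts for e in t.edges]
    return Taxonomy(synsets, edges, metadata={"generator": "synthetic-cohort"})


def _class_inventories(
    tax: Taxonomy,
) -> dict[str, tuple[list[str], np.ndarray]]:
    """Per open class: (lemma list, first-sense depth array)."""
    inv: dict[str, tuple[list[str], np.ndarray]] = {}
    for pos in OPEN_CLASSES:
        lemmas = sorted(
            lemma for (lemma, p) in tax.lemma_index if p == pos
        )
        depths = np.array(
            [tax.depth(tax.lemma_index[(l, pos)][0]) for l in lemmas], float
        )
        if lemmas:
            inv[pos] = (lemmas, depths)
    return inv


def calibrate_depth_preference(
    tax: Taxonomy,
    target_mean: float,
    class_mix: Mapping[str, float] = CLASS_MIX,
    n_tokens: float | None = None,
) -> float:
    """Solve for theta so the expected mean depth of sampled words under
    p(lemma) ~ exp(theta * depth) within each class equals ``target_mean``.

    With ``n_tokens`` None the token-level expectation is matched.  Given a
    token budget, the *type-level* expectation is matched instead — the
    depth average over distinct lemmas expected to occur at least once in
    ``n_tokens`` draws, which is the default weighting of the downstream
    mean-SDI statistic (type means sit above token means when shallow
    words recur, so the two calibrations differ).
    """
    inv = _class_inventories(tax)
    mixes = {c: w for c, w in class_mix.items() if c in inv and w > 0}
    wsum = sum(mixes.values())

    def expected(theta: float) -> float:
        num = den = 0.0
        for c, w in mixes.items():
            d = inv[c][1]
            logw = theta * d
            logw -= logw.max()
            p = np.exp(logw)
            p /= p.sum()
            if n_tokens is None:
                num += (w / wsum) * float(p @ d)
                den += w / wsum
            else:
                n_c = n_tokens * (w / wsum)
                p_obs = -np.expm1(n_c * np.log1p(-np.minimum(p, 1 - 1e-12)))
                num += float(p_obs @ d)
                den += float(p_obs.sum())
        return num / den

    lo, hi = -12.0, 12.0
    e_lo, e_hi = expected(lo), expected(hi)
    if not (min(e_lo, e_hi) <= target_mean <= max(e_lo, e_hi)):
        raise ValueError(
            f"target mean depth {target_mean} outside achievable range "
            f"[{e_lo:.2f}, {e_hi:.2f}]"
        )
    return float(brentq(lambda t: expected(t) - target_mean, lo, hi, xtol=1e-8))


def gen_frequency_lexicon(seed: int, tax: Taxonomy) -> FrequencyLexicon:
    """Frequency-of-use norms (per million) for every taxonomy lemma plus
    the closed-class pool: log-linear decay in depth (generic words are
    frequent) with lognormal scatter."""
    rng = np.random.default_rng([seed, 20])
    entries: dict[tuple[str, str | None], float] = {}
    for pos in OPEN_CLASSES:
        lemmas = sorted(l for (l, p) in tax.lemma_index if p == pos)
        for lemma in lemmas:
            d = tax.depth(tax.lemma_index[(lemma, pos)][0])
            fpm = float(np.exp(np.log(2000.0) - 0.25 * d + rng.normal(0, 0.8)))
            entries[(lemma, pos)] = round(fpm, 4)
    for lemma in CLOSED_CLASS_LEMMAS:
        entries[(lemma, None)] = round(
            float(np.exp(rng.normal(np.log(20000.0), 0.5))), 4
        )
    return FrequencyLexicon(entries)


# ---------------------------------------------------------------------------
# transcript generation

def _resolve_theta(cfg: CohortConfig, tax: Taxonomy) -> dict[str, float]:
    theta: dict[str, float] = {}
    for group in ("svPPA", "lvPPA", "HC"):
        t = cfg.depth_preference.get(group)
        if t is None:
            t = calibrate_depth_preference(
                tax,
                cfg.feature_rates[group]["sdi_target"],
                cfg.class_mix,
                n_tokens=cfg.feature_rates[group]["open_tokens_mean"],
            )
        theta[group] = float(t)
    return theta


def gen_transcripts(cfg: CohortConfig, tax: Taxonomy) -> list[Transcript]:
    """Per-speaker narratives over the five elicitation tasks.

    Open-class lemmas are sampled within each word class with probability
    proportional to exp(theta_g * depth); closed-class tokens come from a
    fixed function-word pool; fillers, false starts, paraphasia tags and
    utterance events are drawn at the configured group rates.
    """
    if not tax.synsets:
        raise ValueError("taxonomy is empty")
    inv = _class_inventories(tax)
    theta = _resolve_theta(cfg, tax)
    classes = [c for c in cfg.class_mix if c in inv and cfg.class_mix[c] > 0]
    mix = np.array([cfg.class_mix[c] for c in classes], float)
    mix /= mix.sum()

    # per-group, per-class sampling distributions
    probs: dict[str, dict[str, np.ndarray]] = {}
    for group, t in theta.items():
        probs[group] = {}
        for c in classes:
            d = inv[c][1]
            logw = t * d
            logw -= logw.max()
            p = np.exp(logw)
            probs[group][c] = p / p.sum()

    lo, hi = cfg.utterance_len
    transcripts: list[Transcript] = []
    for idx, (speaker, group) in enumerate(cfg.roster()):
        rng = np.random.default_rng([cfg.seed, 30, idx])
        rates = cfg.feature_rates[group]
        n_open = max(20, int(round(rng.normal(rates["open_tokens_mean"],
                                              rates["open_tokens_sd"]))))
        n_closed = max(10, int(round(rng.normal(rates["closed_tokens_mean"],
                                                rates["closed_tokens_sd"]))))

        class_draw = rng.choice(len(classes), size=n_open, p=mix)
        tokens: list[Token] = []
        for ci, c in enumerate(classes):
            k = int(np.sum(class_draw == ci))
            if not k:
                continue
            lemma_ids = rng.choice(len(inv[c][0]), size=k, p=probs[group][c])
            lemmas = inv[c][0]
            tokens.extend(
                Token(surface=lemmas[j], lemma=lemmas[j], word_class=c)
                for j in lemma_ids
            )
        # paraphasia tags on distinct open tokens
        n_phon = min(rng.poisson(rates["phonemic_paraphasias"]), len(tokens))
        n_sem = min(rng.poisson(rates["semantic_paraphasias"]), len(tokens))
        tagged = rng.choice(len(tokens), size=n_phon + n_sem, replace=False)
        for pos_i in tagged[:n_phon]:
            t0 = tokens[pos_i]
            tokens[pos_i] = Token(
                surface=t0.surface, lemma=t0.lemma, word_class=t0.word_class,
                error_tags=frozenset({"phonemic_paraphasia"}),
            )
        for pos_i in tagged[n_phon:]:
            t0 = tokens[pos_i]
            tokens[pos_i] = Token(
                surface=t0.surface, lemma=t0.lemma, word_class=t0.word_class,
                error_tags=frozenset({"semantic_paraphasia"}),
            )
        closed_ids = rng.integers(len(CLOSED_CLASS_LEMMAS), size=n_closed)
        tokens.extend(
            Token(surface=CLOSED_CLASS_LEMMAS[j], lemma=CLOSED_CLASS_LEMMAS[j],
                  word_class="closed")
            for j in closed_ids
        )
        for _ in range(rng.poisson(rates["fillers"])):
            f = _FILLERS[rng.integers(len(_FILLERS))]
            tokens.append(Token(surface=f, lemma=f, word_class="filler",
                                excluded=True))
        for _ in range(rng.poisson(rates["false_starts"])):
            frag = CLOSED_CLASS_LEMMAS[rng.integers(len(CLOSED_CLASS_LEMMAS))]
            tokens.append(
                Token(surface=frag + "-", lemma=frag, word_class="closed",
                      error_tags=frozenset({"false_start"}), excluded=True)
            )
        order = rng.permutation(len(tokens))
        tokens = [tokens[j] for j in order]

        # chunk into utterances
        utt_tokens: list[list[Token]] = []
        i = 0
        while i < len(tokens):
            n = int(rng.integers(lo, hi + 1))
            utt_tokens.append(tokens[i:i + n])
            i += n
        n_utt = len(utt_tokens)
        wf = rng.random(n_utt) < rates["well_formed_rate"]
        events: list[list[str]] = [[] for _ in range(n_utt)]
        for _ in range(rng.poisson(rates["anomic_pauses"])):
            events[rng.integers(n_utt)].append("anomic_pause")
        for _ in range(rng.poisson(rates["cda"])):
            events[rng.integers(n_utt)].append("cda")
        utts = [
            Utterance(tokens=tuple(tk), well_formed=bool(w), events=tuple(ev))
            for tk, w, ev in zip(utt_tokens, wf, events)
        ]

        # split across tasks (contiguous blocks, each non-empty)
        weights = np.array([0.30, 0.25, 0.15, 0.10, 0.20])
        bounds = np.floor(np.cumsum(weights) * n_utt).astype(int)
        bounds[-1] = n_utt
        start = 0
        for task, end in zip(TASKS, bounds):
            end = max(end, start + 1)
            end = min(end, n_utt)
            if start >= n_utt:
                break
            transcripts.append(
                Transcript(speaker_id=speaker, group=group, task=task,
                           utterances=tuple(utts[start:end]))
            )
            start = end
        if start < n_utt:  # remainder joins the last emitted task
            last = transcripts.pop()
            transcripts.append(
                Transcript(
                    speaker_id=speaker, group=group, task=last.task,
                    utterances=last.utterances + tuple(utts[start:]),
                )
            )
    return transcripts


# ---------------------------------------------------------------------------
# thickness generation

def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1) if v.size > 1 else 0.0
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def gen_thickness(
    cfg: CohortConfig,
    profiles: Sequence[FeatureProfile] | None = None,
) -> ThicknessTable:
    """Draw the cohort's regional thickness table (see CohortConfig).

    ``profiles`` supply the clinical speakers' mean SDI; they are required
    whenever the link is active (non-empty ``link_rois`` with
    ``link_r != 0``).  Controls are always drawn from their group normals.
    """
    # pooled mode keeps its designated ROIs on the pooled baseline even at
    # r=0 (exact independence for null calibration); group_anchored with
    # r=0 degenerates to plain per-group draws
    link_active = bool(cfg.link_rois) and (
        cfg.link_r != 0.0 or cfg.link_mode == "pooled"
    )
    roster = cfg.roster()
    clinical = [(s, g) for s, g in roster if g != "HC"]
    sdi: dict[str, float] = {}
    if bool(cfg.link_rois) and cfg.link_r != 0.0:
        if profiles is None:
            raise ValueError("profiles required when the SDI link is active")
        sdi = {p.speaker_id: float(p.mean_sdi) for p in profiles}
        missing = [s for s, _ in clinical if s not in sdi]
        if missing:
            raise ValueError(f"profiles missing for speaker(s): {missing}")

    rng = np.random.default_rng([cfg.seed, 40])
    link_set = set(cfg.link_rois)
    n_clin = len(clinical)
    records: list[dict] = []
    for region in DESIKAN_REGIONS:
        for hemi in HEMISPHERES:
            params = cfg.thickness[(region, hemi)]
            linked = link_active and (region, hemi) in link_set and clinical
            if linked:
                if sdi:
                    x = np.array([sdi[s] for s, _ in clinical])
                    z = _zscore(x)
                else:  # r = 0: the coupling term vanishes
                    x = np.zeros(n_clin)
                    z = np.zeros(n_clin)
                eps = rng.standard_normal(n_clin)
                resid = np.sqrt(max(0.0, 1.0 - cfg.link_r**2))
                if cfg.link_mode == "pooled":
                    w = np.array(
                        [cfg.n_sv, cfg.n_lv], float
                    ) / max(1, n_clin)
                    m = w[0] * params["svPPA"][0] + w[1] * params["lvPPA"][0]
                    sd = w[0] * params["svPPA"][1] + w[1] * params["lvPPA"][1]
                    vals = m + sd * (cfg.link_r * z + resid * eps)
                    for (s, _g), v in zip(clinical, vals):
                        records.append((s, _g, region, hemi, float(v)))
                else:  # group_anchored: per-group mean/SD preserved
                    for g in ("svPPA", "lvPPA"):
                        members = [i for i, (_s, gg) in enumerate(clinical)
                                   if gg == g]
                        if not members:
                            continue
                        m, sd = params[g]
                        zg = _zscore(x[members])
                        vals = m + sd * (cfg.link_r * zg
                                         + resid * eps[members])
                        for i, v in zip(members, vals):
                            s, gg = clinical[i]
                            records.append((s, gg, region, hemi, float(v)))
            else:
                for s, g in clinical:
                    m, sd = params[g]
                    records.append(
                        (s, g, region, hemi, float(rng.normal(m, sd)))
                    )
            m, sd = params["HC"]
            for s, g in roster:
                if g == "HC":
                    records.append(
                        (s, g, region, hemi, float(rng.normal(m, sd)))
                    )
    df = pd.DataFrame(
        records, columns=["subject", "group", "region", "hemi", "thickness_mm"]
    )
    # keep subject-major ordering for readable output
    order = {s: i for i, (s, _g) in enumerate(roster)}
    df = df.sort_values(
        ["subject"], key=lambda col: col.map(order), kind="stable"
    ).reset_index(drop=True)
    return ThicknessTable(df)


# ---------------------------------------------------------------------------

def simulate_cohort(cfg: CohortConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write all four pipeline inputs; returns the file map.

    Files: taxonomy.tsv, transcripts.tsv, frequency.tsv, thickness.tsv and
    a cohort.yml echo of the configuration.
    """
    from .features import extract_features
    from .transcripts import merge_speaker
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tax = default_taxonomy(cfg.seed)
    lex = gen_frequency_lexicon(cfg.seed, tax)
    transcripts = gen_transcripts(cfg, tax)
    profiles = []
    for speaker, group in cfg.roster():
        if group == "HC":
            continue
        mine = [t for t in transcripts if t.speaker_id == speaker]
        profiles.append(extract_features(merge_speaker(mine, speaker), tax, lex))
    tt = gen_thickness(cfg, profiles)

    paths = {
        "taxonomy": outdir / "taxonomy.tsv",
        "transcripts": outdir / "transcripts.tsv",
        "frequency": outdir / "frequency.tsv",
        "thickness": outdir / "thickness.tsv",
        "config": outdir / "cohort.yml",
    }
    write_taxonomy(tax, paths["taxonomy"])
    write_transcripts(transcripts, paths["transcripts"])
    lex.write(paths["frequency"])
    write_thickness(tt, paths["thickness"])
    echo = asdict(cfg)
    echo["thickness"] = {
        f"{r}/{h}": {g: list(ms) for g, ms in v.items()}
        for (r, h), v in echo["thickness"].items()
    }
    echo["link_rois"] = [list(x) for x in cfg.link_rois]
    paths["config"].write_text(
        yaml.safe_dump(echo, sort_keys=True), encoding="utf-8"
    )
    return paths
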