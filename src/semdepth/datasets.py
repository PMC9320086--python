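"""Built-in fixtures: the worked-example taxonomy and reference scores."""

from __future__ import annotations

from importlib import resources

from .taxonomy import Taxonomy, load_taxonomy

__all__ = ["cat_taxonomy", "load_individual_sdi_scores"]


def _data_path(name: str):
    return resources.files("semdepth").joinpath("data", name)


def cat_taxonomy() -> Taxonomy:
    """The worked-example hypernym tree for "cat".

    A WordNet-style noun chain from the root "entity" down to "cat", with
    the canonical depth anchors thing=1, animal=3, cat=10, plus a small
    verb component (close=1, come out=3) showing that each word class is
    rooted in its own tree.
    """
    with resources.as_file(_data_path("cat_hierarchy.tsv")) as p:
        return load_taxonomy(p)


def load_individual_sdi_scores() -> dict[str, list[float]]:
    """Synthetic per-patient mean-SDI scores for the two clinical groups.

    The original per-patient appendix scores are not redistributable;
    these SYNTHETIC stand-ins were constructed to reproduce the published
    group summaries exactly (svPPA n=6: mean 3.99, SD 0.32; lvPPA n=16:
    mean 4.42, SD 0.37; Mann-Whitney U = 19.0, exact two-sided p = 0.033).
    Individual values are not real measurements.
    """
    scores: dict[str, list[float]] = {}
    with resources.as_file(_data_path("individual_sdi_synthetic.tsv")) as p:
        with open(p, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#") or line.startswith("group\t"):
                    continue
                group, _speaker, val = line.split("\t")
                scores.setdefault(group, []).append(float(val))
    return scores
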