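"""Hypernym taxonomy model and the Semantic Depth Index (SDI).

A taxonomy is a directed acyclic graph of synsets (sets of synonymous
lemmas) linked by "is-a" (hyponym -> hypernym) edges, as in WordNet-style
lexical databases.  The SDI of a produced word is the number of nodes
separating its synset from the root of its word class, root excluded —
equivalently, the number of hypernym edges on the shortest path from the
synset up to any root.  Low SDI marks generic terms ("thing", "animal"),
high SDI specific ones ("cat").

File dialect (UTF-8, tab-separated, ``#`` comments)::

    S<TAB>id<TAB>pos<TAB>lemma1|lemma2...<TAB>gloss
    E<TAB>hyponym_id<TAB>hypernym_id

The writer re-emits the same dialect bit-exactly (records sorted by id).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "POS_TAGS",
    "OPEN_CLASSES",
    "SENSE_POLICIES",
    "Synset",
    "SdiValue",
    "Taxonomy",
    "TaxonomyError",
    "TaxonomyParseError",
    "TaxonomyCycleError",
    "UnknownSynsetError",
    "ResourceMissingError",
    "load_taxonomy",
    "write_taxonomy",
    "synset_depth",
    "sdi_for_word",
    "coverage_report",
    "build_from_wordnet_resource",
]

POS_TAGS = ("noun", "verb", "adjective", "adverb")
OPEN_CLASSES = POS_TAGS  # open word classes coincide with taxonomy pos tags
SENSE_POLICIES = ("first_sense", "min_depth", "max_depth", "mean_depth")


class TaxonomyError(ValueError):
    """Base class for taxonomy construction and lookup errors."""


class TaxonomyParseError(TaxonomyError):
    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class TaxonomyCycleError(TaxonomyError):
    def __init__(self, synset_id: str):
        super().__init__(f"hypernym graph contains a cycle through synset {synset_id!r}")
        self.synset_id = synset_id


class UnknownSynsetError(TaxonomyError):
    pass


class ResourceMissingError(TaxonomyError):
    pass


@dataclass(frozen=True)
class Synset:
    """One concept node: an id, a word class and its synonymous lemmas.

    Lemma order encodes sense rank for ``first_sense`` resolution: the
    first synset listed for a lemma in the lemma index is its sense 1.
    """

    id: str
    pos: str
    lemmas: tuple[str, ...]
    gloss: str = ""

    def __post_init__(self) -> None:
        if self.pos not in POS_TAGS:
            raise TaxonomyError(f"synset {self.id!r}: unknown pos {self.pos!r}")
        if not self.lemmas:
            raise TaxonomyError(f"synset {self.id!r}: empty lemma list")


@dataclass(frozen=True)
class SdiValue:
    """SDI lookup result for one (lemma, pos) query.

    ``sdi`` is an ``int`` except under the ``mean_depth`` policy, where the
    average over senses is reported exactly as a :class:`fractions.Fraction`.
    ``found=False`` means the lemma has no synset of that pos; the word is
    then skipped from mean-SDI aggregation, never imputed.
    """

    lemma: str
    pos: str
    found: bool
    sdi: int | Fraction | None = None
    synset_used: str | None = None
    policy_used: str | None = None


class Taxonomy:
    """Validated rooted DAG of synsets with a lemma index and depth table."""

    def __init__(
        self,
        synsets: Iterable[Synset],
        edges: Iterable[tuple[str, str]],
        metadata: Mapping[str, str] | None = None,
    ):
        self.synsets: dict[str, Synset] = {}
        for s in synsets:
            if s.id in self.synsets:
                raise TaxonomyError(f"duplicate synset id {s.id!r}")
            self.synsets[s.id] = s
        self.edges: list[tuple[str, str]] = []
        for hypo, hyper in edges:
            for end in (hypo, hyper):
                if end not in self.synsets:
                    raise TaxonomyError(f"edge references unknown synset {end!r}")
            if self.synsets[hypo].pos != self.synsets[hyper].pos:
                raise TaxonomyError(
                    f"is-a edge crosses word classes: {hypo!r} -> {hyper!r}"
                )
            self.edges.append((hypo, hyper))
        self.metadata: dict[str, str] = dict(metadata or {})

        g = nx.DiGraph()
        g.add_nodes_from(self.synsets)
        g.add_edges_from(self.edges)  # hyponym -> hypernym
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise TaxonomyCycleError(cycle[0][0])
        self._graph = g

        self.roots: dict[str, set[str]] = {pos: set() for pos in POS_TAGS}
        for sid, syn in self.synsets.items():
            if g.out_degree(sid) == 0:
                self.roots[syn.pos].add(sid)

        # min hypernym edges from each synset up to any root of its pos
        rev = g.reverse(copy=False)
        self._depth: dict[str, int] = {}
        for pos, roots in self.roots.items():
            if not roots:
                continue
            lengths = nx.multi_source_dijkstra_path_length(rev, roots)
            for sid, d in lengths.items():
                if self.synsets[sid].pos == pos:
                    self._depth[sid] = int(d)
        orphans = set(self.synsets) - set(self._depth)
        if orphans:
            sid = sorted(orphans)[0]
            raise TaxonomyError(
                f"synset {sid!r} cannot reach a root of its word class"
            )

        # (lemma, pos) -> synset ids in sense-rank order (file order)
        self.lemma_index: dict[tuple[str, str], tuple[str, ...]] = {}
        acc: dict[tuple[str, str], list[str]] = {}
        for sid in self.synsets:  # insertion order = file order
            syn = self.synsets[sid]
            for lemma in syn.lemmas:
                acc.setdefault((lemma.casefold(), syn.pos), []).append(sid)
        self.lemma_index = {k: tuple(v) for k, v in acc.items()}

    def __len__(self) -> int:
        return len(self.synsets)

    def depth(self, synset_id: str) -> int:
        if synset_id not in self.synsets:
            raise UnknownSynsetError(f"unknown synset id {synset_id!r}")
        return self._depth[synset_id]

    def synsets_for(self, lemma: str, pos: str) -> tuple[str, ...]:
        return self.lemma_index.get((lemma.casefold(), pos), ())


def synset_depth(t: Taxonomy, synset_id: str) -> int:
    """Minimum number of hypernym edges from ``synset_id`` to any root of
    its word class (root itself -> 0)."""
    return t.depth(synset_id)


def sdi_for_word(
    t: Taxonomy, lemma: str, pos: str, policy: str = "first_sense"
) -> SdiValue:
    """Resolve a lemma's SDI under a sense policy.

    Polysemous lemmas map to several synsets; ``first_sense`` takes sense
    rank 1, ``min_depth``/``max_depth`` the extreme depths, ``mean_depth``
    the exact average (a Fraction).  Absence is a ``found=False`` result,
    not an error.
    """
    if policy not in SENSE_POLICIES:
        raise TaxonomyError(f"unknown sense policy {policy!r}")
    if pos not in POS_TAGS:
        raise TaxonomyError(f"unknown pos {pos!r}")
    senses = t.synsets_for(lemma, pos)
    if not senses:
        return SdiValue(lemma=lemma, pos=pos, found=False, policy_used=policy)
    depths = [(t.depth(sid), sid) for sid in senses]
    if policy == "first_sense":
        d, sid = depths[0]
    elif policy == "min_depth":
        d, sid = min(depths)
    elif policy == "max_depth":
        d, sid = max(depths)
    else:  # mean_depth
        d = Fraction(sum(dd for dd, _ in depths), len(depths))
        if d.denominator == 1:
            d = int(d)
        sid = None
    return SdiValue(
        lemma=lemma, pos=pos, found=True, sdi=d, synset_used=sid, policy_used=policy
    )


def coverage_report(
    t: Taxonomy, lemmas: Sequence[tuple[str, str]]
) -> dict:
    """Per-pos found/missing counts for a list of (lemma, pos) queries.

    Returns ``{"n": ..., "found": ..., "coverage": float | None,
    "per_pos": {pos: {"found": ..., "missing": ...}}, "missing": [...]}``;
    ``coverage`` is None (undefined) for an empty query list.
    """
    per_pos = {pos: {"found": 0, "missing": 0} for pos in POS_TAGS}
    missing: list[tuple[str, str]] = []
    n_found = 0
    for lemma, pos in lemmas:
        if t.synsets_for(lemma, pos):
            per_pos[pos]["found"] += 1
            n_found += 1
        else:
            per_pos[pos]["missing"] += 1
            missing.append((lemma, pos))
    n = len(lemmas)
    return {
        "n": n,
        "found": n_found,
        "coverage": (n_found / n) if n else None,
        "per_pos": per_pos,
        "missing": missing,
    }


def load_taxonomy(path: str | Path) -> Taxonomy:
    """Read a taxonomy from the tab-separated edge-list dialect."""
    synsets: list[Synset] = []
    edges: list[tuple[str, str]] = []
    metadata: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                if line.startswith("#!"):  # metadata comment: #! key value
                    parts = line[2:].strip().split(None, 1)
                    if len(parts) == 2:
                        metadata[parts[0]] = parts[1]
                continue
            fields = line.split("\t")
            kind = fields[0]
            if kind == "S":
                if len(fields) not in (4, 5):
                    raise TaxonomyParseError(
                        f"S record needs 4-5 fields, got {len(fields)}", lineno
                    )
                sid, pos, lemma_field = fields[1], fields[2], fields[3]
                gloss = fields[4] if len(fields) == 5 else ""
                if pos not in POS_TAGS:
                    raise TaxonomyParseError(f"unknown pos {pos!r}", lineno)
                lemmas = tuple(l for l in lemma_field.split("|") if l)
                if not lemmas:
                    raise TaxonomyParseError("empty lemma list", lineno)
                try:
                    synsets.append(Synset(id=sid, pos=pos, lemmas=lemmas, gloss=gloss))
                except TaxonomyError as exc:
                    raise TaxonomyParseError(str(exc), lineno) from exc
            elif kind == "E":
                if len(fields) != 3:
                    raise TaxonomyParseError(
                        f"E record needs 3 fields, got {len(fields)}", lineno
                    )
                edges.append((fields[1], fields[2]))
            else:
                raise TaxonomyParseError(f"unknown record type {kind!r}", lineno)
    return Taxonomy(synsets, edges, metadata)


def write_taxonomy(t: Taxonomy, path: str | Path) -> None:
    """Write the canonical dialect: metadata, then S records sorted by id,
    then E records sorted by (hyponym, hypernym).  Bit-exact re-readable."""
    lines: list[str] = []
    for key in sorted(t.metadata):
        lines.append(f"#! {key} {t.metadata[key]}")
    for sid in sorted(t.synsets):
        s = t.synsets[sid]
        lines.append("\t".join(["S", s.id, s.pos, "|".join(s.lemmas), s.gloss]))
    for hypo, hyper in sorted(t.edges):
        lines.append("\t".join(["E", hypo, hyper]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def build_from_wordnet_resource(resource: str = "wordnet") -> Taxonomy:
    """Optional adapter: convert an installed WordNet-format corpus (via
    nltk) into a Taxonomy over its noun and verb hypernym graphs.

    The corpus version string is recorded in ``Taxonomy.metadata``.  When
    the resource is unavailable, raises :class:`ResourceMissingError`
    explaining how to supply an edge-list file instead.
    """
    guidance = (
        "WordNet-format resource unavailable; supply the taxonomy as an "
        "edge-list file (S/E records, see load_taxonomy) instead"
    )
    try:
        from nltk.corpus import wordnet as wn  # type: ignore

        wn.ensure_loaded()
    except Exception as exc:  # ImportError or missing corpus download
        raise ResourceMissingError(f"{guidance}: {exc}") from exc

    pos_map = {"n": "noun", "v": "verb"}
    synsets: list[Synset] = []
    edges: list[tuple[str, str]] = []
    for wn_pos, pos in pos_map.items():
        for ss in wn.all_synsets(wn_pos):
            lemmas = tuple(l.name().replace("_", " ") for l in ss.lemmas())
            synsets.append(Synset(id=ss.name(), pos=pos, lemmas=lemmas,
                                  gloss=ss.definition() or ""))
            for hyper in ss.hypernyms() + ss.instance_hypernyms():
                edges.append((ss.name(), hyper.name()))
    version = getattr(wn, "get_version", lambda: "unknown")()
    return Taxonomy(synsets, edges, metadata={"wordnet_version": str(version)})
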