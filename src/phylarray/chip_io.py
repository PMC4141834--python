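"""Data model and readers/writers for phylogenetic-microarray experiments.

The on-disk formats are deliberately plain: tab-separated UTF-8 tables with a
mandatory header row and ``.`` as the decimal separator, plus Newick for the
reference tree.  Five tables describe an experiment:

* probe annotation: ``probe_id, otu_id, species_id, at_count`` — one row per
  (probe, OTU) assignment; the same probe may be assigned to several OTUs
  (that sharing is what cross-hybridization adjustment discounts), but never
  twice to the same OTU;
* taxonomy: ``otu_id, lineage`` with a semicolon-delimited six-rank lineage
  (phylum;class;order;family;genus;species), empty ranks read as
  ``unclassified``;
* intensities (long format): ``sample_id, replicate_id, condition_label,
  probe_id, pm, mm`` — control/spike-in probes carry the ``CTRL_`` prefix and
  are routed to :attr:`SampleArray.spikein`;
* sample metadata is implicit in the intensity table's ``condition_label``;
* a rooted Newick tree over ``otu_id`` leaves with non-negative branch
  lengths.
"""

from __future__ import annotations

import io
import math
from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd
from skbio import TreeNode

CONTROL_PREFIX = "CTRL_"
RANK_NAMES = ("phylum", "class", "order", "family", "genus", "species")
UNCLASSIFIED = "unclassified"


class ChipIOError(ValueError):
    """Base class for file-format and validation failures."""


class ParseError(ChipIOError):
    """Malformed file content (names the offending line where possible)."""


class ValidationError(ChipIOError):
    """Well-formed content violating a domain invariant."""


class ProbePair(NamedTuple):
    """One PM/MM 25-mer probe pair.

    ``pm``/``mm`` are fluorescence intensities (arbitrary units, >= 0 after
    background handling); ``at_count`` is the number of A and T bases in the
    PM probe, which determines the probe's background-binning during response
    scoring.  Reference (annotation-level) pairs carry ``pm = mm = 0.0`` until
    joined with a :class:`SampleArray`.
    """

    probe_id: str
    at_count: int
    pm: float = 0.0
    mm: float = 0.0

    def validate(self) -> "ProbePair":
        if not (0 <= self.at_count <= 25):
            raise ValidationError(
                f"probe {self.probe_id!r}: at_count {self.at_count} outside 0-25"
            )
        for name, v in (("pm", self.pm), ("mm", self.mm)):
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"probe {self.probe_id!r}: {name}={v!r} invalid")
        return self


@dataclass(frozen=True)
class ProbeSet:
    """All probe pairs assigned to one OTU (sub-species bin).

    Several OTUs may share a ``species_id``; presence at stage 2 of the
    calling procedure is decided per species.
    """

    otu_id: str
    species_id: str
    pairs: tuple[ProbePair, ...]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValidationError(f"OTU {self.otu_id!r}: empty probe set")
        seen = set()
        for p in self.pairs:
            if p.probe_id in seen:
                raise ValidationError(
                    f"OTU {self.otu_id!r}: duplicate probe {p.probe_id!r}"
                )
            seen.add(p.probe_id)

    @property
    def probe_ids(self) -> tuple[str, ...]:
        return tuple(p.probe_id for p in self.pairs)


@dataclass
class SampleArray:
    """One chip: intensities of one biological replicate of one sample."""

    sample_id: str
    replicate_id: str
    condition_label: str
    intensities: "OrderedDict[str, tuple[float, float]]"
    spikein: dict[str, float] = field(default_factory=dict)

    @property
    def array_id(self) -> str:
        return f"{self.sample_id}/{self.replicate_id}"


@dataclass(frozen=True)
class TaxonomyLineage:
    """Six-rank lineage (phylum..species) of one OTU; gaps are 'unclassified'."""

    otu_id: str
    ranks: tuple[str, str, str, str, str, str]

    def __post_init__(self) -> None:
        if len(self.ranks) != len(RANK_NAMES):
            raise ValidationError(
                f"OTU {self.otu_id!r}: lineage needs {len(RANK_NAMES)} ranks, "
                f"got {len(self.ranks)}"
            )

    @property
    def species(self) -> str:
        return self.ranks[-1]

    def rank(self, name: str) -> str:
        return self.ranks[RANK_NAMES.index(name)]


@dataclass
class ReferenceSet:
    """Chip design: probe sets, taxonomy and (optionally) the reference tree."""

    probesets: "OrderedDict[str, ProbeSet]"
    taxonomy: "OrderedDict[str, TaxonomyLineage]"
    tree_source: str | None = None

    def __post_init__(self) -> None:
        if self.taxonomy:
            missing = [o for o in self.probesets if o not in self.taxonomy]
            if missing:
                raise ValidationError(
                    f"OTUs without taxonomy lineage: {missing[:5]}"
                )
        if self.tree_source is not None:
            tree = parse_newick(self.tree_source, self)
            self._tree = tree

    @property
    def otu_ids(self) -> tuple[str, ...]:
        return tuple(self.probesets)

    def probes_to_otus(self) -> dict[str, set[str]]:
        """Map probe_id -> set of OTUs whose probe sets contain it."""
        out: dict[str, set[str]] = {}
        for ps in self.probesets.values():
            for pid in ps.probe_ids:
                out.setdefault(pid, set()).add(ps.otu_id)
        return out

    def tree(self) -> TreeNode:
        if self.tree_source is None:
            raise ValidationError("reference set has no tree")
        return parse_newick(self.tree_source, self)


# ---------------------------------------------------------------------------
# readers


def _read_tsv(path, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas message
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return df


def _to_float(value: str, path, row: int, col: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise ParseError(
            f"{path}: line {row + 2}: column {col!r} value {value!r} is not a number"
        ) from None


def read_probe_annotation(path, taxonomy_path=None) -> ReferenceSet:
    """Read a probe-annotation table (and optional taxonomy) into a ReferenceSet.

    Rows sharing an ``otu_id`` form that OTU's probe set, in file order.
    ``at_count`` must lie in 0-25; a probe listed twice for the same OTU is
    rejected.
    """
    df = _read_tsv(path, ["probe_id", "otu_id", "species_id", "at_count"])
    by_otu: "OrderedDict[str, list[ProbePair]]" = OrderedDict()
    species: dict[str, str] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            at = int(row.at_count)
        except ValueError:
            raise ParseError(
                f"{path}: line {i + 2}: at_count {row.at_count!r} is not an integer"
            ) from None
        pair = ProbePair(row.probe_id, at).validate()
        if row.otu_id in species and species[row.otu_id] != row.species_id:
            raise ValidationError(
                f"{path}: line {i + 2}: OTU {row.otu_id!r} maps to two species"
            )
        species[row.otu_id] = row.species_id
        by_otu.setdefault(row.otu_id, []).append(pair)
    probesets = OrderedDict(
        (otu, ProbeSet(otu, species[otu], tuple(pairs)))
        for otu, pairs in by_otu.items()
    )
    taxonomy: "OrderedDict[str, TaxonomyLineage]" = OrderedDict()
    if taxonomy_path is not None:
        taxonomy = read_taxonomy(taxonomy_path)
    return ReferenceSet(probesets, taxonomy)


def read_taxonomy(path) -> "OrderedDict[str, TaxonomyLineage]":
    df = _read_tsv(path, ["otu_id", "lineage"])
    out: "OrderedDict[str, TaxonomyLineage]" = OrderedDict()
    for i, row in enumerate(df.itertuples(index=False)):
        ranks = [r.strip() or UNCLASSIFIED for r in row.lineage.split(";")]
        if len(ranks) != len(RANK_NAMES):
            raise ParseError(
                f"{path}: line {i + 2}: lineage has {len(ranks)} ranks, "
                f"expected {len(RANK_NAMES)}"
            )
        if row.otu_id in out:
            raise ValidationError(f"{path}: duplicate taxonomy for {row.otu_id!r}")
        out[row.otu_id] = TaxonomyLineage(row.otu_id, tuple(ranks))
    return out


def read_intensity_table(
    path, reference: ReferenceSet | None = None
) -> tuple[list[SampleArray], list[str]]:
    """Read a long-format intensity table into one SampleArray per replicate.

    Returns ``(arrays, warnings)``.  Probes absent from the reference are kept
    but reported as warnings (they may be controls of an unknown layout);
    negative intensities and duplicate (replicate, probe) rows are errors.
    """
    df = _read_tsv(
        path,
        ["sample_id", "replicate_id", "condition_label", "probe_id", "pm", "mm"],
    )
    known = set(reference.probes_to_otus()) if reference is not None else None
    arrays: "OrderedDict[tuple[str, str], SampleArray]" = OrderedDict()
    warnings: list[str] = []
    warned: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        pm = _to_float(row.pm, path, i, "pm")
        mm = _to_float(row.mm, path, i, "mm")
        if pm < 0 or mm < 0:
            raise ValidationError(
                f"{path}: line {i + 2}: negative intensity for {row.probe_id!r}"
            )
        key = (row.sample_id, row.replicate_id)
        arr = arrays.get(key)
        if arr is None:
            arr = SampleArray(
                row.sample_id, row.replicate_id, row.condition_label, OrderedDict()
            )
            arrays[key] = arr
        elif arr.condition_label != row.condition_label:
            raise ValidationError(
                f"{path}: line {i + 2}: replicate {key} has two condition labels"
            )
        if row.probe_id.startswith(CONTROL_PREFIX):
            if row.probe_id in arr.spikein:
                raise ValidationError(
                    f"{path}: line {i + 2}: duplicate control {row.probe_id!r}"
                )
            arr.spikein[row.probe_id] = pm
            continue
        if row.probe_id in arr.intensities:
            raise ValidationError(
                f"{path}: line {i + 2}: duplicate probe {row.probe_id!r} "
                f"in replicate {key}"
            )
        if known is not None and row.probe_id not in known:
            if row.probe_id not in warned:
                warnings.append(f"probe {row.probe_id!r} not in reference")
                warned.add(row.probe_id)
        arr.intensities[row.probe_id] = (pm, mm)
    return list(arrays.values()), warnings


def parse_newick(text: str, reference: ReferenceSet | None = None) -> TreeNode:
    """Parse and validate a rooted Newick string.

    The tree must be rooted (exactly two children at the root — a basal
    trifurcation is the conventional signature of an unrooted tree and is
    rejected rather than silently midpoint-rooted), branch lengths must be
    non-negative, leaves unique, and — when a reference is given — a subset of
    its OTU ids.
    """
    try:
        tree = TreeNode.read(io.StringIO(text), convert_underscores=False)
    except Exception as exc:
        raise ParseError(f"invalid Newick: {exc}") from exc
    if len(tree.children) != 2:
        raise ValidationError(
            f"tree root has {len(tree.children)} children; a rooted (bifurcating"
            " at the root) tree is required"
        )
    seen: set[str] = set()
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
        if node.length < 0:
            raise ValidationError(f"negative branch length {node.length}")
        if node.is_tip():
            if node.name in seen:
                raise ValidationError(f"duplicate leaf {node.name!r}")
            seen.add(node.name)
    if reference is not None:
        extra = seen - set(reference.otu_ids)
        if extra:
            raise ValidationError(
                f"tree leaves not in reference: {sorted(extra)[:5]}"
            )
    return tree


def read_newick(path, reference: ReferenceSet | None = None) -> TreeNode:
    with open(path, encoding="utf-8") as fh:
        return parse_newick(fh.read(), reference)


# ---------------------------------------------------------------------------
# writers (inverse of the readers; round-trip safe)


def write_probe_annotation(reference: ReferenceSet, path) -> None:
    rows = [
        (p.probe_id, ps.otu_id, ps.species_id, p.at_count)
        for ps in reference.probesets.values()
        for p in ps.pairs
    ]
    pd.DataFrame(rows, columns=["probe_id", "otu_id", "species_id", "at_count"]).to_csv(
        path, sep="\t", index=False
    )


def write_taxonomy(taxonomy: Mapping[str, TaxonomyLineage], path) -> None:
    rows = [(lin.otu_id, ";".join(lin.ranks)) for lin in taxonomy.values()]
    pd.DataFrame(rows, columns=["otu_id", "lineage"]).to_csv(path, sep="\t", index=False)


def write_intensity_table(arrays: Iterable[SampleArray], path) -> None:
    rows = []
    for arr in arrays:
        for pid, (pm, mm) in arr.intensities.items():
            rows.append(
                (arr.sample_id, arr.replicate_id, arr.condition_label,
                 pid, repr(pm), repr(mm))
            )
        for pid, v in arr.spikein.items():
            rows.append(
                (arr.sample_id, arr.replicate_id, arr.condition_label,
                 pid, repr(v), "0.0")
            )
    pd.DataFrame(
        rows,
        columns=["sample_id", "replicate_id", "condition_label", "probe_id", "pm", "mm"],
    ).to_csv(path, sep="\t", index=False)


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")
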