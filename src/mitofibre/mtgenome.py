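"""Mitochondrial genome coordinate engine and deletion annotation.

Coordinates are 1-based inclusive on the revised Cambridge Reference
Sequence (rCRS, NC_012920.1, 16,569 bp, circular). A deletion is described
by its two breakpoints: ``bp5`` is the last retained base on the 5' side
and ``bp3`` the first retained base on the 3' side, so the removed bases
are the open interval (bp5, bp3), i.e. bp5+1 .. bp3-1, and the deletion
size is ``bp3 - bp5 - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

RCRS_LENGTH = 16569

FEATURE_KINDS = frozenset(
    {"protein_gene", "tRNA", "rRNA", "origin", "control_region"}
)

#: Features every usable map must carry.
REQUIRED_FEATURES = frozenset(
    {"MT-ND1", "MT-ND4", "MT-CO1", "MT-CO2", "MT-CO3", "O_L", "control_region"}
)

# rCRS (NC_012920.1) coordinates, 1-based inclusive. The control region
# wraps the origin of the numbering (16024..576).
_DEFAULT_FEATURES: tuple[tuple[str, int, int, str], ...] = (
    ("control_region", 16024, 576, "control_region"),
    ("MT-RNR1", 648, 1601, "rRNA"),
    ("MT-RNR2", 1671, 3229, "rRNA"),
    ("MT-ND1", 3307, 4262, "protein_gene"),
    ("MT-ND2", 4470, 5511, "protein_gene"),
    ("O_L", 5721, 5798, "origin"),
    ("MT-CO1", 5904, 7445, "protein_gene"),
    ("MT-CO2", 7586, 8269, "protein_gene"),
    ("MT-ATP8", 8366, 8572, "protein_gene"),
    ("MT-ATP6", 8527, 9207, "protein_gene"),
    ("MT-CO3", 9207, 9990, "protein_gene"),
    ("MT-ND3", 10059, 10404, "protein_gene"),
    ("MT-ND4L", 10470, 10766, "protein_gene"),
    ("MT-ND4", 10760, 12137, "protein_gene"),
    ("MT-ND5", 12337, 14148, "protein_gene"),
    ("MT-ND6", 14149, 14673, "protein_gene"),
    ("MT-CYB", 14747, 15887, "protein_gene"),
)


class GenomeMapError(ValueError):
    """Raised for invalid feature maps or coordinates."""


class DeletionError(ValueError):
    """Raised for invalid deletion breakpoints."""


@dataclass(frozen=True)
class GenomeFeature:
    """A named feature on the circular genome (1-based inclusive span)."""

    name: str
    start: int
    end: int
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise GenomeMapError(
                f"{self.name}: unknown feature kind {self.kind!r}"
            )
        if self.start < 1 or self.end < 1:
            raise GenomeMapError(f"{self.name}: positions must be >= 1")
        if self.start > self.end and self.kind != "control_region":
            raise GenomeMapError(
                f"{self.name}: start > end only allowed for the "
                "origin-wrapping control region"
            )

    @property
    def wraps(self) -> bool:
        return self.start > self.end


@dataclass(frozen=True)
class GenomeMap:
    """A validated set of features on a circular genome."""

    genome_length: int = RCRS_LENGTH
    features: tuple[GenomeFeature, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise GenomeMapError(f"duplicate feature names: {dupes}")
        missing = REQUIRED_FEATURES - set(names)
        if missing:
            raise GenomeMapError(f"map lacks required features: {sorted(missing)}")
        for f in self.features:
            if f.start > self.genome_length or f.end > self.genome_length:
                raise GenomeMapError(
                    f"{f.name}: span {f.start}-{f.end} exceeds genome "
                    f"length {self.genome_length}"
                )

    def feature(self, name: str) -> GenomeFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def positions(self, name: str) -> range | tuple[range, range]:
        """Positions covered by a feature; two ranges if it wraps."""
        f = self.feature(name)
        if f.wraps:
            return (range(f.start, self.genome_length + 1), range(1, f.end + 1))
        return range(f.start, f.end + 1)


@dataclass(frozen=True)
class DeletionEvent:
    """A sequenced deletion: last retained 5' base and first retained 3' base."""

    cell_id: str
    product_id: str
    bp5: int
    bp3: int

    def __post_init__(self) -> None:
        if self.bp5 >= self.bp3:
            raise DeletionError(
                f"{self.product_id}: bp5 ({self.bp5}) must be < bp3 "
                f"({self.bp3}); origin-wrapping deletions are not supported"
            )
        if self.bp3 - self.bp5 < 2:
            raise DeletionError(
                f"{self.product_id}: breakpoints {self.bp5}/{self.bp3} "
                "delimit an empty deletion"
            )


@dataclass(frozen=True)
class DeletionAnnotation:
    """What a deletion removes from the genome."""

    size_bp: int
    removed_interval: tuple[int, int]  # open interval (bp5, bp3)
    genes_fully_removed: frozenset[str]
    genes_partially_removed: frozenset[str]
    ol_removed: bool
    minor_arc_overlap: bool
    nd1_removed: bool
    nd4_removed: bool
    any_cox_removed: bool


def deletion_size(bp5: int, bp3: int) -> int:
    """Size in bp of the deletion with retained flanks ending/starting at bp5/bp3.

    The removed bases are the open interval (bp5, bp3), so the size is
    ``bp3 - bp5 - 1``.
    """
    if bp5 >= bp3 - 1:
        raise DeletionError(
            f"breakpoints {bp5}/{bp3} delimit an empty or invalid deletion"
        )
    return bp3 - bp5 - 1


def load_genome_map(map_source: str | Path | None = None) -> GenomeMap:
    """Load a feature map, or return the built-in rCRS default.

    ``map_source`` is a 4-column whitespace/tab table (name, start, end,
    kind) with 1-based inclusive positions. Note this dialect is NOT
    standard BED (which is 0-based half-open); see :func:`read_bed` /
    :func:`write_bed` for strict BED interchange.
    """
    if map_source is None:
        feats = tuple(GenomeFeature(*row) for row in _DEFAULT_FEATURES)
        return GenomeMap(RCRS_LENGTH, feats)
    df = pd.read_csv(
        map_source,
        sep=r"\s+",
        comment="#",
        names=["name", "start", "end", "kind"],
        dtype={"name": str, "kind": str},
    )
    feats = tuple(
        GenomeFeature(r.name, int(r.start), int(r.end), r.kind)
        for r in df.itertuples(index=False)
    )
    return GenomeMap(RCRS_LENGTH, feats)


def read_bed(path: str | Path, genome_length: int = RCRS_LENGTH) -> GenomeMap:
    """Read a strict BED (0-based half-open) feature map.

    A feature that wraps the origin appears in BED as two intervals with
    the same name (one ending at the genome length, one starting at 0);
    such pairs are merged back into a single wrapping feature.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#",
        names=["chrom", "start", "end", "name", "kind"],
        dtype={"chrom": str, "name": str, "kind": str},
    )
    segments: dict[str, list] = {}
    for r in df.itertuples(index=False):
        segments.setdefault(r.name, []).append(r)
    feats = []
    for name, segs in segments.items():
        if len(segs) == 1:
            r = segs[0]
            feats.append(GenomeFeature(name, int(r.start) + 1, int(r.end), r.kind))
        elif len(segs) == 2:
            tail = next((s for s in segs if int(s.end) == genome_length), None)
            head = next((s for s in segs if int(s.start) == 0), None)
            if tail is None or head is None:
                raise GenomeMapError(
                    f"{name}: split feature segments do not meet at the origin"
                )
            feats.append(
                GenomeFeature(name, int(tail.start) + 1, int(head.end), tail.kind)
            )
        else:
            raise GenomeMapError(f"{name}: more than two BED segments")
    return GenomeMap(genome_length, tuple(feats))


def write_bed(gmap: GenomeMap, path: str | Path, chrom: str = "chrM") -> None:
    """Write a strict BED (0-based half-open) file; wrapping features split."""
    rows = []
    for f in gmap.features:
        if f.wraps:
            rows.append((chrom, f.start - 1, gmap.genome_length, f.name, f.kind))
            rows.append((chrom, 0, f.end, f.name, f.kind))
        else:
            rows.append((chrom, f.start - 1, f.end, f.name, f.kind))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def _overlap_removed(feature: GenomeFeature, bp5: int, bp3: int,
                     genome_length: int) -> tuple[bool, bool]:
    """(fully_removed, partially_removed) for a feature vs open interval (bp5, bp3)."""
    removed = set(range(bp5 + 1, bp3))
    if feature.wraps:
        span = set(range(feature.start, genome_length + 1)) | set(
            range(1, feature.end + 1)
        )
    else:
        span = set(range(feature.start, feature.end + 1))
    inter = span & removed
    if not inter:
        return False, False
    if inter == span:
        return True, False
    return False, True


def annotate_deletion(d: DeletionEvent, gmap: GenomeMap) -> DeletionAnnotation:
    """Annotate which features a deletion removes, fully or partially.

    A feature is fully removed iff its whole span lies inside the open
    interval (bp5, bp3); it is partially removed iff it overlaps the
    interval without being contained.
    """
    fully: set[str] = set()
    partially: set[str] = set()
    for f in gmap.features:
        full, part = _overlap_removed(f, d.bp5, d.bp3, gmap.genome_length)
        if full:
            fully.add(f.name)
        elif part:
            partially.add(f.name)

    removed_any = fully | partially
    nd1 = "MT-ND1" in removed_any
    nd4 = "MT-ND4" in removed_any
    cox = bool({"MT-CO1", "MT-CO2", "MT-CO3"} & removed_any)
    ol_removed = "O_L" in fully

    # Minor arc: between the control-region 3' end and the O_L start.
    cr = gmap.feature("control_region")
    ol = gmap.feature("O_L")
    minor = GenomeFeature("minor_arc", cr.end + 1, ol.start - 1, "origin")
    m_full, m_part = _overlap_removed(minor, d.bp5, d.bp3, gmap.genome_length)

    return DeletionAnnotation(
        size_bp=deletion_size(d.bp5, d.bp3),
        removed_interval=(d.bp5, d.bp3),
        genes_fully_removed=frozenset(fully),
        genes_partially_removed=frozenset(partially),
        ol_removed=ol_removed,
        minor_arc_overlap=m_full or m_part,
        nd1_removed=nd1,
        nd4_removed=nd4,
        any_cox_removed=cox,
    )


def expected_triplex_class(a: DeletionAnnotation) -> str:
    """Deletion class the triplex qPCR assay should report for this deletion.

    Partial removal counts as removed: the assay's probe sites lie inside
    MT-ND1 / MT-ND4 and most breakpoints truncate genes.
    """
    if a.nd1_removed and a.nd4_removed:
        return "both"
    if a.nd4_removed:
        return "ND4_deleted"
    if a.nd1_removed:
        return "ND1_deleted"
    return "none"


def read_deletion_table(path: str | Path) -> list[DeletionEvent]:
    """Read a deletion CSV (cell_id, product_id, bp5, bp3)."""
    df = pd.read_csv(path, dtype={"cell_id": str, "product_id": str})
    return [
        DeletionEvent(str(r.cell_id), str(r.product_id), int(r.bp5), int(r.bp3))
        for r in df.itertuples(index=False)
    ]


def annotate_table(
    deletions: Iterable[DeletionEvent], gmap: GenomeMap | None = None
) -> pd.DataFrame:
    """Annotate many deletions into a tidy frame."""
    gmap = gmap or load_genome_map()
    rows = []
    for d in deletions:
        a = annotate_deletion(d, gmap)
        rows.append(
            {
                "cell_id": d.cell_id,
                "product_id": d.product_id,
                "bp5": d.bp5,
                "bp3": d.bp3,
                "size_bp": a.size_bp,
                "genes_fully_removed": ";".join(sorted(a.genes_fully_removed)),
                "genes_partially_removed": ";".join(
                    sorted(a.genes_partially_removed)
                ),
                "ol_removed": a.ol_removed,
                "minor_arc_overlap": a.minor_arc_overlap,
                "expected_triplex_class": expected_triplex_class(a),
            }
        )
    return pd.DataFrame(rows)
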