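"""Barrier-truncation variant design.

A barrier region — a rigid segment occluding the substrate binding cleft —
is deleted as an inclusive author-numbered range and bridged with a short
flexible linker (Gly-Gly by default).  Variants are renumbered sequentially
1..N; the old→new residue-number map is the bridge back to parent numbering
(needed, e.g., to locate the catalytic serine after truncation).

Packaged constants provide the five barrier regions per enzyme for the two
BHET hydrolases this workflow was developed around (BsEst and ChryBHETase).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

log = logging.getLogger(__name__)

DEFAULT_LINKER = "GG"


class VariantDesignError(ValueError):
    """Invalid truncation request."""


@dataclass(frozen=True)
class BarrierRegion:
    """An inclusive author-numbered residue range to delete."""

    label: str
    start: int
    end: int
    chain: str = "A"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise VariantDesignError(
                f"region {self.label}: start {self.start} > end {self.end}"
            )

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass
class TruncationVariant:
    """A truncated sequence with its old→new residue-number map."""

    parent_id: str
    region: BarrierRegion
    linker: str
    sequence: str
    removed_count: int
    number_map: dict[int, int | None]

    @property
    def variant_id(self) -> str:
        return f"{self.parent_id}-{self.region.label}"


def _load_builtin() -> dict[str, list[BarrierRegion]]:
    text = resources.files("barriereng.data").joinpath("barrier_regions.yaml").read_text()
    raw = yaml.safe_load(text)
    out: dict[str, list[BarrierRegion]] = {}
    for enzyme, regions in raw.items():
        if enzyme == "version":
            continue
        out[enzyme] = [
            BarrierRegion(label=r["label"], start=r["start"], end=r["end"])
            for r in regions
        ]
    return out


_BUILTIN = _load_builtin()
BSEST_REGIONS: list[BarrierRegion] = _BUILTIN["bsest"]
CHRYBHETASE_REGIONS: list[BarrierRegion] = _BUILTIN["chrybhetase"]


def builtin_regions(name: str) -> list[BarrierRegion]:
    """Packaged region sets by enzyme name ('bsest' or 'chrybhetase')."""
    try:
        return list(_BUILTIN[name.lower()])
    except KeyError:
        raise KeyError(
            f"no builtin region set {name!r}; available: {sorted(_BUILTIN)}"
        ) from None


def design_truncation(
    parent_seq: str,
    region: BarrierRegion,
    linker: str = DEFAULT_LINKER,
    numbering: list[int] | None = None,
    parent_id: str = "parent",
) -> TruncationVariant:
    """Delete ``region`` from ``parent_seq`` and insert ``linker`` in its place.

    ``numbering`` gives the author number of each sequence position
    (default 1..len).  The variant is renumbered sequentially 1..N; the
    returned ``number_map`` sends every parent author number to its new
    number, or ``None`` for deleted positions.
    """
    if numbering is None:
        numbering = list(range(1, len(parent_seq) + 1))
    if len(numbering) != len(parent_seq):
        raise VariantDesignError("numbering length must match sequence length")
    index_of = {num: i for i, num in enumerate(numbering)}
    if region.start not in index_of or region.end not in index_of:
        raise VariantDesignError(
            f"region {region.label} ({region.start}-{region.end}) outside parent "
            f"numbering {numbering[0]}-{numbering[-1]}"
        )
    i0, i1 = index_of[region.start], index_of[region.end]
    prefix, suffix = parent_seq[:i0], parent_seq[i1 + 1:]
    sequence = prefix + linker + suffix
    removed = i1 - i0 + 1
    shift = len(linker) - removed
    number_map: dict[int, int | None] = {}
    for i, num in enumerate(numbering):
        if i < i0:
            number_map[num] = i + 1
        elif i <= i1:
            number_map[num] = None
        else:
            number_map[num] = i + 1 + shift
    return TruncationVariant(
        parent_id=parent_id,
        region=region,
        linker=linker,
        sequence=sequence,
        removed_count=removed,
        number_map=number_map,
    )


def batch_design(
    parent_seq: str,
    regions: list[BarrierRegion],
    linker: str = DEFAULT_LINKER,
    numbering: list[int] | None = None,
    parent_id: str = "parent",
) -> list[TruncationVariant]:
    """One independent variant per region (regions may overlap)."""
    variants = []
    for region in regions:
        try:
            variants.append(
                design_truncation(parent_seq, region, linker, numbering, parent_id)
            )
        except VariantDesignError as exc:
            raise VariantDesignError(f"region {region.label}: {exc}") from exc
    return variants


def map_residue(variant: TruncationVariant, old_number: int) -> int | None:
    """New residue number for a parent author number; None if deleted."""
    try:
        return variant.number_map[old_number]
    except KeyError:
        raise VariantDesignError(
            f"residue {old_number} is outside the parent numbering"
        ) from None


def write_variants(variants: list[TruncationVariant], path: str | Path) -> None:
    """Write variants as FASTA, header ``parent|label|start-end|linker``."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    if not variants:
        log.warning("writing empty variant FASTA to %s", path)
    records = [
        SeqRecord(
            Seq(v.sequence),
            id=f"{v.parent_id}|{v.region.label}|{v.region.start}-{v.region.end}|{v.linker}",
            description="",
        )
        for v in variants
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
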