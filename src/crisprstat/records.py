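"""Record types for CRISPR array and cas-operon annotation tables.

A CRISPR *array* is a locus of alternating direct repeats and spacers on a
replicon; its size is counted in spacers.  A *cas operon* is the cluster of
CRISPR-associated genes, anchored here by the near-universal adaptation gene
cas1 and labelled with its class/type/subtype from the 2015 classification
scheme.  An :class:`IntegratedSystem` joins one operon to the array with the
smallest base-pair distance on the same replicon (the *proximal* array); all
other arrays on the replicon are carried along as *trans* arrays.

Coordinates are 1-based inclusive throughout, following the convention of
the public CRISPR database exports these tables emulate.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

VALID_STRANDS = ("+", "-", "?")
VALID_REPLICON_KINDS = ("chromosome", "plasmid")
VALID_CLASSES = (1, 2)
VALID_TYPES = ("I", "III", "IV", "other")


class ValidationError(ValueError):
    """A record violates one of its structural invariants."""


@dataclass(frozen=True)
class ArrayRecord:
    """One annotated CRISPR array on a replicon.

    ``start_bp``/``end_bp`` are 1-based inclusive and must lie within the
    replicon; ``n_spacers`` is the array size (>= 1 for annotated arrays);
    ``questionable`` marks putative arrays of uncertain validity, which are
    retained at read time and removed only by explicit filtering.
    """

    accession: str
    organism: str
    replicon_kind: str
    replicon_length: int
    array_id: str
    start_bp: int
    end_bp: int
    n_spacers: int
    strand: str
    questionable: bool

    def __post_init__(self) -> None:
        if self.replicon_kind not in VALID_REPLICON_KINDS:
            raise ValidationError(
                f"replicon_kind {self.replicon_kind!r} not in {VALID_REPLICON_KINDS}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"strand {self.strand!r} not in {VALID_STRANDS}")
        if self.replicon_length <= 0:
            raise ValidationError(f"replicon_length must be positive, got {self.replicon_length}")
        if not (1 <= self.start_bp <= self.end_bp <= self.replicon_length):
            raise ValidationError(
                f"array {self.array_id} on {self.accession}: coordinates "
                f"[{self.start_bp}, {self.end_bp}] violate "
                f"1 <= start <= end <= replicon_length ({self.replicon_length})"
            )
        if self.n_spacers < 1:
            raise ValidationError(
                f"array {self.array_id} on {self.accession}: n_spacers must be >= 1, "
                f"got {self.n_spacers}"
            )


@dataclass(frozen=True)
class CasOperon:
    """One cas1-anchored operon with its classification labels."""

    accession: str
    system_class: int
    system_type: str
    subtype: Optional[str]
    operon_start_bp: int
    operon_end_bp: int
    strand: str
    has_cas1: bool

    def __post_init__(self) -> None:
        if self.system_class not in VALID_CLASSES:
            raise ValidationError(
                f"system_class {self.system_class!r} not in {VALID_CLASSES}"
            )
        if self.system_type not in VALID_TYPES:
            raise ValidationError(
                f"system_type {self.system_type!r} not in {VALID_TYPES}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"strand {self.strand!r} not in {VALID_STRANDS}")
        if self.operon_start_bp > self.operon_end_bp:
            raise ValidationError(
                f"operon on {self.accession}: start {self.operon_start_bp} > "
                f"end {self.operon_end_bp}"
            )
        if self.subtype is not None and self.system_type != "other":
            prefix = self.subtype.split("-", 1)[0]
            if prefix != self.system_type:
                raise ValidationError(
                    f"subtype {self.subtype!r} inconsistent with "
                    f"system_type {self.system_type!r}"
                )


@dataclass(frozen=True)
class IntegratedSystem:
    """A cas operon joined to its proximal CRISPR array.

    ``distance_bp`` is 0 when the operon and array intervals overlap,
    otherwise the gap between the nearest interval ends.  ``trans_arrays``
    holds every other array on the replicon, paired with its distance and
    sorted by increasing distance (ties by smaller start coordinate).
    """

    operon: CasOperon
    proximal_array: ArrayRecord
    distance_bp: int
    trans_arrays: Tuple[Tuple[ArrayRecord, int], ...] = ()

    def __post_init__(self) -> None:
        if self.distance_bp < 0:
            raise ValidationError("distance_bp must be non-negative")
        if self.proximal_array.accession != self.operon.accession:
            raise ValidationError("proximal array and operon accessions differ")
        for arr, d in self.trans_arrays:
            if arr.accession != self.operon.accession:
                raise ValidationError("trans array accession differs from operon")
            if d < self.distance_bp:
                raise ValidationError(
                    "trans array closer than the proximal array"
                )

    @property
    def accession(self) -> str:
        return self.operon.accession

    @property
    def n_arrays_on_replicon(self) -> int:
        return 1 + len(self.trans_arrays)


@dataclass(frozen=True)
class FilterCriteria:
    """Inclusion rules applied jointly to the array and cas tables.

    Defaults encode the study's rules: chromosomal loci only, questionable
    structures removed, Class 1 Type I/III systems with a cas1 anchor.
    """

    allow_replicon_kinds: frozenset = frozenset({"chromosome"})
    exclude_questionable: bool = True
    allowed_classes: frozenset = frozenset({1})
    allowed_types: frozenset = frozenset({"I", "III"})
    require_cas1: bool = True

    def __post_init__(self) -> None:
        if not self.allow_replicon_kinds:
            raise ValidationError("allow_replicon_kinds must be non-empty")
        if not self.allowed_classes:
            raise ValidationError("allowed_classes must be non-empty")
        if not self.allowed_types:
            raise ValidationError("allowed_types must be non-empty")
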