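"""Affinity records, mutation-string grammar and dataset-level protocol.

The target quantity throughout is the change in Gibbs free energy of
binding upon mutation, ddG = dG_wt - dG_mut in kcal/mol: negative values
destabilize (reduce affinity), positive values stabilize.  This module
implements the dataset-construction rules around that convention:

* the mutation-string grammar ``"chain WTresnumMUT"`` with ';' joining
  the sites of a multiple-point construct;
* conversion of dissociation constants to ddG (dG = RT ln K_D);
* hypothetical reverse-mutation augmentation (ddG_mut->wt = -ddG_wt->mut)
  restricted to forward records with ddG >= -2 kcal/mol, since large
  destabilizations imply structural changes a modelled mutant cannot
  capture;
* neutral-band direction labelling (-0.5 <= ddG <= 0.5 neutral, both
  boundaries inclusive);
* alanine-scanning hot-spot labelling at a configurable cutoff;
* additive-vs-synergistic classification of multiple-point constructs;
* complex-level group ids for group-aware cross-validation (forward and
  reverse partners always share a group).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import pandas as pd

from .errors import MutationValidationError, NotClassifiableError
from .structure_io import AA_1TO3, NucleicAcidType

#: gas constant in kcal/(mol K)
R_KCAL = 1.98720425e-3
DEFAULT_TEMPERATURE = 298.15

AA_LETTERS = set(AA_1TO3)


@dataclass(frozen=True)
class MutationSpec:
    """One point mutation: chain, wild-type letter, residue number, mutant letter."""

    chain_id: str
    wt: str
    residue_number: int
    mut: str
    insertion_code: str = ""

    def __post_init__(self) -> None:
        if self.wt not in AA_LETTERS or self.mut not in AA_LETTERS:
            raise MutationValidationError(
                f"non-standard amino acid in {self.wt}{self.residue_number}{self.mut}")

    @property
    def site(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)

    def __str__(self) -> str:
        return (f"{self.chain_id} {self.wt}{self.residue_number}"
                f"{self.insertion_code}{self.mut}")

    def reversed(self) -> "MutationSpec":
        return replace(self, wt=self.mut, mut=self.wt)


@dataclass(frozen=True)
class MutationConstruct:
    """An ordered collection of one or more point mutations applied jointly."""

    specs: tuple[MutationSpec, ...]

    def __post_init__(self) -> None:
        if not self.specs:
            raise MutationValidationError("empty mutation construct")
        sites = [s.site for s in self.specs]
        if len(set(sites)) != len(sites):
            raise MutationValidationError(
                f"duplicate mutation site in construct {self}")

    def __len__(self) -> int:
        return len(self.specs)

    def __iter__(self):
        return iter(self.specs)

    def __str__(self) -> str:
        return ";".join(str(s) for s in self.specs)


_SPEC_RE = re.compile(
    r"^(?P<chain>\S) (?P<wt>[A-Z])(?P<num>\d+)(?P<icode>[A-Za-z]?)(?P<mut>[A-Z])$")


def parse_mutation_spec(text: str, allow_self: bool = False) -> MutationSpec:
    m = _SPEC_RE.match(text.strip())
    if not m:
        raise MutationValidationError(
            f"malformed mutation {text!r}: expected 'chain WTresnumMUT' "
            "with a single space after the chain identifier")
    spec = MutationSpec(chain_id=m.group("chain"), wt=m.group("wt"),
                        residue_number=int(m.group("num")),
                        mut=m.group("mut"),
                        insertion_code=m.group("icode"))
    if spec.wt == spec.mut and not allow_self:
        raise MutationValidationError(
            f"wild-type and mutant are identical in {text!r}")
    return spec


def parse_mutation_string(text: str) -> MutationConstruct:
    """Parse ``"A R45G"`` or ``"A R45G;A K50A"`` into a construct.

    Grammar: CONSTRUCT := SPEC (';' SPEC)*; SPEC := CHAIN ' ' WT NUM [ICODE]
    MUT.  Whitespace around ';' is tolerated.  Errors carry the column
    position of the offending specification.
    """
    if not text or not text.strip():
        raise MutationValidationError("empty mutation string")
    specs = []
    col = 0
    for part in text.split(";"):
        try:
            specs.append(parse_mutation_spec(part))
        except MutationValidationError as exc:
            raise MutationValidationError(
                f"{exc} (at column {col + len(part) - len(part.lstrip())})"
            ) from None
        col += len(part) + 1
    return MutationConstruct(specs=tuple(specs))


def kd_to_ddg(kd_wt: float, kd_mut: float,
              temperature: float = DEFAULT_TEMPERATURE) -> float:
    """ddG (kcal/mol) from dissociation constants: RT ln(kd_wt / kd_mut)."""
    if kd_wt <= 0 or kd_mut <= 0:
        raise ValueError("dissociation constants must be positive")
    return R_KCAL * temperature * math.log(kd_wt / kd_mut)


@dataclass
class AffinityRecord:
    """One mutation construct with its experimental or derived ddG."""

    complex_id: str
    construct: MutationConstruct
    ddg: float
    na_type: NucleicAcidType | None = None
    provenance: str = "experimental"       # experimental | reverse
    group_id: str = ""
    forward_ref: str | None = None         # id of the forward partner, if reverse
    kd_wt: float | None = None
    kd_mut: float | None = None
    temperature: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.ddg):
            raise ValueError("ddG must be finite")
        if not self.group_id:
            self.group_id = self.complex_id

    @property
    def record_id(self) -> str:
        tag = "rev" if self.provenance == "reverse" else "fwd"
        return f"{self.complex_id}:{self.construct}:{tag}"

    @property
    def is_single(self) -> bool:
        return len(self.construct) == 1


@dataclass
class AffinityDataset:
    """A collection of affinity records with complex-level grouping."""

    records: list[AffinityRecord] = field(default_factory=list)
    schema_version: str = "1"

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def groups(self) -> list[str]:
        return [r.group_id for r in self.records]

    def by_complex(self) -> dict[str, list[AffinityRecord]]:
        out: dict[str, list[AffinityRecord]] = {}
        for r in self.records:
            out.setdefault(r.complex_id, []).append(r)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "complex_id": [r.complex_id for r in self.records],
            "mutation": [str(r.construct) for r in self.records],
            "ddg": [r.ddg for r in self.records],
            "na_type": [r.na_type.kind if r.na_type else "" for r in self.records],
            "provenance": [r.provenance for r in self.records],
            "group_id": [r.group_id for r in self.records],
        })

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AffinityDataset":
        records = []
        for _, row in frame.iterrows():
            records.append(AffinityRecord(
                complex_id=str(row["complex_id"]),
                construct=parse_mutation_string(str(row["mutation"])),
                ddg=float(row["ddg"]),
                na_type=(NucleicAcidType(row["na_type"])
                         if row.get("na_type") else None),
                provenance=str(row.get("provenance", "experimental")),
                group_id=str(row.get("group_id", "") or row["complex_id"]),
            ))
        return cls(records=records)


REVERSE_DDG_FLOOR = -2.0


def augment_with_reverse(dataset: AffinityDataset,
                         mutant_builder=None,
                         floor: float = REVERSE_DDG_FLOOR) -> AffinityDataset:
    """Append hypothetical reverse mutations to balance the dataset.

    For each single-point experimental record with ddG >= ``floor``
    (boundary inclusive, default -2 kcal/mol) a reverse record is
    appended with ddG negated, provenance ``reverse`` and the same group
    id.  Records below the floor gain no partner: their mutants are too
    perturbed for a modelled reverse structure to be trustworthy.
    ``mutant_builder``, when given, is called with the forward record and
    may raise to veto a reverse record (build failures are skipped with a
    logged reason).
    """
    import logging

    logger = logging.getLogger(__name__)
    out = list(dataset.records)
    for rec in dataset.records:
        if rec.provenance != "experimental" or not rec.is_single:
            continue
        if rec.ddg < floor:
            continue
        if mutant_builder is not None:
            try:
                mutant_builder(rec)
            except Exception as exc:  # noqa: BLE001 - build failures skip the record
                logger.warning("skipping reverse of %s: mutant build failed (%s)",
                               rec.record_id, exc)
                continue
        spec = rec.construct.specs[0]
        out.append(AffinityRecord(
            complex_id=rec.complex_id,
            construct=MutationConstruct(specs=(spec.reversed(),)),
            ddg=-rec.ddg,
            na_type=rec.na_type,
            provenance="reverse",
            group_id=rec.group_id,
            forward_ref=rec.record_id,
        ))
    return AffinityDataset(records=out, schema_version=dataset.schema_version)


NEUTRAL_BAND = (-0.5, 0.5)


def label_direction(ddg: float, band: tuple[float, float] = NEUTRAL_BAND) -> str:
    """increasing / neutral / decreasing affinity (band boundaries neutral)."""
    lo, hi = band
    if lo <= ddg <= hi:
        return "neutral"
    return "decreasing" if ddg < lo else "increasing"


def label_hotspot(record: AffinityRecord, cutoff: float) -> str:
    """Alanine-scanning hot-spot label at the given ddG cutoff.

    Only single-point mutations to alanine participate in the hot-spot
    benchmark; everything else is ``not-applicable``.
    """
    if not record.is_single or record.construct.specs[0].mut != "A":
        return "not-applicable"
    return "hot-spot" if record.ddg <= cutoff else "non-hot-spot"


def classify_additivity(multi: AffinityRecord,
                        singles: list[AffinityRecord],
                        criterion: str = "abs_0.2") -> str:
    """Additive vs synergistic classification of a multi-point construct.

    ``abs_0.2``: additive iff |ddG_multi - sum(singles)| < 0.2 kcal/mol;
    ``rel_10pct``: additive iff that difference is < 10% of |sum(singles)|.
    Every site of the construct must be covered by a single-point record.
    """
    if criterion not in ("abs_0.2", "rel_10pct"):
        raise ValueError(f"unknown criterion {criterion!r}")
    by_site = {}
    for s in singles:
        if s.is_single:
            spec = s.construct.specs[0]
            by_site[(spec.site, spec.mut)] = s
    total = 0.0
    for spec in multi.construct:
        key = (spec.site, spec.mut)
        if key not in by_site:
            raise NotClassifiableError(
                f"no single-point record for site {spec} of {multi.record_id}")
        total += by_site[key].ddg
    diff = abs(multi.ddg - total)
    if criterion == "abs_0.2":
        return "additive" if diff < 0.2 else "synergistic"
    return "additive" if diff < 0.10 * abs(total) else "synergistic"
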