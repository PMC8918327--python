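"""Curated SLiM catalog for the SYDE interactor screen.

The default catalog packages the motif classes used to predict SYDE1/SYDE2
binding partners: for each class, the published consensus text, a machine
pattern (restricted regex, see :mod:`sydeslim.patterns`), the published ELM
probability score (metadata only — the scanner computes its own background
score), interactor/pathway annotations, and the published motif instances
with their 1-based coordinates.  Docking-derived substrate rows (RhoA/RhoB)
are not motif classes; they are carried separately for the network stage,
as are point sites (palmitoylation, NES candidates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .patterns import CompiledPattern, PatternError, compile_pattern, match_at
from .seqio import ProteinRecord, locate_peptide

KINDS = ("ligand-site", "modification-site", "docking-site", "degron")


class CatalogError(ValueError):
    """Structurally invalid catalog."""


@dataclass(frozen=True)
class MotifInstance:
    """A published occurrence of a motif class in a SYDE protein."""

    motif_id: str
    protein_id: str
    start: int
    end: int
    peptide: str

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.peptide):
            raise CatalogError(
                f"instance {self.motif_id}/{self.protein_id} {self.start}..{self.end}: "
                f"span {self.end - self.start + 1} != peptide length {len(self.peptide)} "
                f"({self.peptide!r})"
            )


@dataclass(frozen=True)
class MotifClass:
    """A SLiM consensus with interactor metadata."""

    motif_id: str
    elm_class: str
    interactor: str
    consensus_text: str
    pattern: str
    kind: str
    elm_score_printed: float | None = None
    pathway: str = ""
    category: str = "uncategorized"
    molecule_class: str = "other"
    compiled: CompiledPattern = field(compare=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise CatalogError(f"{self.motif_id}: unknown kind {self.kind!r}")
        if self.elm_score_printed is not None and not (0.0 < self.elm_score_printed < 1.0):
            raise CatalogError(f"{self.motif_id}: printed score outside (0,1)")
        if self.compiled is None:
            try:
                object.__setattr__(self, "compiled", compile_pattern(self.pattern))
            except PatternError as exc:
                raise CatalogError(f"{self.motif_id}: {exc}") from exc


@dataclass(frozen=True)
class SiteAnnotationEntry:
    """A point or short-interval site that is annotated, not scanned."""

    protein_id: str
    site_type: str  # palmitoylation | phosphosite | NES
    positions: tuple[int, ...]
    peptide: str = ""
    source: str = ""


@dataclass(frozen=True)
class StructuralPrediction:
    """A docking-derived substrate edge (enters the network, bypasses the scanner)."""

    proteins: tuple[str, ...]
    interactor: str
    region: str
    category: str = "Rho-family modulator"
    molecule_class: str = "GTPase"
    pathway: str = ""


@dataclass(frozen=True)
class Catalog:
    classes: tuple[MotifClass, ...]
    instances: tuple[MotifInstance, ...]
    sites: tuple[SiteAnnotationEntry, ...] = ()
    structural: tuple[StructuralPrediction, ...] = ()
    version: int = 1

    def get_class(self, motif_id: str) -> MotifClass:
        for c in self.classes:
            if c.motif_id == motif_id:
                return c
        raise KeyError(motif_id)

    def instances_of(self, motif_id: str) -> list[MotifInstance]:
        return [i for i in self.instances if i.motif_id == motif_id]


def default_catalog_path() -> Path:
    return Path(resources.files("sydeslim").joinpath("data/motif_catalog.yaml"))  # type: ignore[arg-type]


def load_catalog(path: str | Path | None = None) -> Catalog:
    """Load the packaged default catalog, or one from ``path``.

    Raises :class:`CatalogError` on duplicate motif ids or on an instance
    whose coordinate span disagrees with its peptide length.  An empty
    catalog file yields empty lists with a warning.
    """
    src = Path(path) if path is not None else default_catalog_path()
    doc = yaml.safe_load(src.read_text())
    if not doc or not doc.get("classes"):
        warnings.warn(f"{src}: empty motif catalog", stacklevel=2)
        return Catalog(classes=(), instances=())

    classes: list[MotifClass] = []
    instances: list[MotifInstance] = []
    seen: set[str] = set()
    for entry in doc["classes"]:
        motif_id = entry["motif_id"]
        if motif_id in seen:
            raise CatalogError(f"duplicate motif_id {motif_id!r}")
        seen.add(motif_id)
        classes.append(
            MotifClass(
                motif_id=motif_id,
                elm_class=entry["elm_class"],
                interactor=entry.get("interactor", ""),
                consensus_text=entry.get("consensus_text", ""),
                pattern=entry["pattern"],
                kind=entry["kind"],
                elm_score_printed=entry.get("elm_score_printed"),
                pathway=entry.get("pathway", "") or "",
                category=entry.get("category", "uncategorized"),
                molecule_class=entry.get("molecule_class", "other"),
            )
        )
        for inst in entry.get("instances", []):
            instances.append(
                MotifInstance(
                    motif_id=motif_id,
                    protein_id=inst["protein_id"],
                    start=int(inst["start"]),
                    end=int(inst["end"]),
                    peptide=str(inst["peptide"]).upper(),
                )
            )
    sites = tuple(
        SiteAnnotationEntry(
            protein_id=s["protein_id"],
            site_type=s["site_type"],
            positions=tuple(int(p) for p in s["positions"]),
            peptide=str(s.get("peptide", "")).upper(),
            source=s.get("source", ""),
        )
        for s in doc.get("site_annotations", [])
    )
    structural = tuple(
        StructuralPrediction(
            proteins=tuple(s["proteins"]),
            interactor=s["interactor"],
            region=s.get("region", ""),
            category=s.get("category", "Rho-family modulator"),
            molecule_class=s.get("molecule_class", "GTPase"),
            pathway=s.get("pathway", ""),
        )
        for s in doc.get("structural_predictions", [])
    )
    return Catalog(
        classes=tuple(classes),
        instances=tuple(instances),
        sites=sites,
        structural=structural,
        version=int(doc.get("version", 1)),
    )


def save_catalog(catalog: Catalog, path: str | Path) -> None:
    """Serialize a catalog back to the YAML schema (lossless round-trip)."""
    doc: dict = {"version": catalog.version, "classes": []}
    for c in catalog.classes:
        entry: dict = {
            "motif_id": c.motif_id,
            "elm_class": c.elm_class,
            "interactor": c.interactor,
            "consensus_text": c.consensus_text,
            "pattern": c.pattern,
            "kind": c.kind,
            "pathway": c.pathway,
            "category": c.category,
            "molecule_class": c.molecule_class,
            "instances": [
                {"protein_id": i.protein_id, "start": i.start, "end": i.end,
                 "peptide": i.peptide}
                for i in catalog.instances_of(c.motif_id)
            ],
        }
        if c.elm_score_printed is not None:
            entry["elm_score_printed"] = c.elm_score_printed
        doc["classes"].append(entry)
    if catalog.sites:
        doc["site_annotations"] = [
            {"protein_id": s.protein_id, "site_type": s.site_type,
             "positions": list(s.positions), "peptide": s.peptide, "source": s.source}
            for s in catalog.sites
        ]
    if catalog.structural:
        doc["structural_predictions"] = [
            {"proteins": list(s.proteins), "interactor": s.interactor,
             "region": s.region, "category": s.category,
             "molecule_class": s.molecule_class, "pathway": s.pathway}
            for s in catalog.structural
        ]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False, allow_unicode=True))


@dataclass(frozen=True)
class ValidationIssue:
    motif_id: str
    protein_id: str
    check: str  # "pattern-vs-instance" | "coordinate"
    detail: str


@dataclass(frozen=True)
class ValidationReport:
    n_classes: int
    n_instances: int
    pattern_checks_passed: int
    coordinate_checks_passed: int
    coordinate_checks_run: int
    issues: tuple[ValidationIssue, ...]

    @property
    def passed(self) -> bool:
        return not self.issues


def validate_catalog(
    catalog: Catalog,
    sequences: Mapping[str, ProteinRecord] | Sequence[ProteinRecord] | None = None,
) -> ValidationReport:
    """Check the catalog's central invariant and, optionally, coordinates.

    (a) pattern-vs-instance: each class pattern must match somewhere inside
    every packaged instance peptide of that class; (b) when a sequence is
    supplied for an instance's protein, the peptide must occur at its
    recorded start.  Failures are reported, never raised.
    """
    seq_map: dict[str, ProteinRecord] = {}
    if sequences is not None:
        records = sequences.values() if isinstance(sequences, Mapping) else sequences
        for r in records:
            seq_map[r.id] = r
            if r.accession:
                seq_map.setdefault(r.accession, r)

    issues: list[ValidationIssue] = []
    pattern_ok = 0
    coord_ok = 0
    coord_run = 0
    for inst in catalog.instances:
        cls = catalog.get_class(inst.motif_id)
        hit = any(
            match_at(cls.compiled, inst.peptide, p)
            for p in range(len(inst.peptide))
        )
        if hit:
            pattern_ok += 1
        else:
            issues.append(
                ValidationIssue(inst.motif_id, inst.protein_id, "pattern-vs-instance",
                                f"pattern {cls.pattern!r} has no match in {inst.peptide!r}")
            )
        rec = seq_map.get(inst.protein_id)
        if rec is not None:
            coord_run += 1
            if inst.start in locate_peptide(rec, inst.peptide):
                coord_ok += 1
            else:
                issues.append(
                    ValidationIssue(inst.motif_id, inst.protein_id, "coordinate",
                                    f"{inst.peptide!r} not found at {inst.start} in "
                                    f"{rec.id!r}")
                )
    return ValidationReport(
        n_classes=len(catalog.classes),
        n_instances=len(catalog.instances),
        pattern_checks_passed=pattern_ok,
        coordinate_checks_passed=coord_ok,
        coordinate_checks_run=coord_run,
        issues=tuple(issues),
    )
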