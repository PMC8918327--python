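"""Synthetic ortholog-family generator with ground truth.

Families emulate the structure the screen relies on: a root protein with
compositionally biased disordered segments (charge/Ser/Pro-enriched,
aromatic/aliphatic-depleted) and globular segments, motif instances
implanted at known coordinates, and orthologs derived by per-site
substitution at a background rate ``q_bg`` (a lower ``q_motif`` inside
conserved implants; deliberate disruption for non-conserved ones).
Indels are off by default and not simulated, so the emitted "alignment"
is the trivial column-per-residue one; truth is always *recomputed* from
the emitted sequences by pattern matching, never assumed from provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import Catalog
from .conservation import MultipleAlignment
from .patterns import CompiledPattern, match_at
from .scanner import BackgroundFrequencies, SWISSPROT_COMPOSITION
from .seqio import AMINO_ACIDS, ProteinRecord

#: composition multipliers defining the two segment classes
DISORDER_ENRICH = {"E": 2.2, "S": 2.2, "P": 2.2, "K": 2.2, "Q": 2.2, "R": 2.2,
                   "W": 0.25, "F": 0.25, "I": 0.25, "L": 0.25, "V": 0.25,
                   "C": 0.25, "M": 0.25}
ORDER_ENRICH = {"W": 1.8, "F": 1.8, "I": 1.8, "L": 1.8, "V": 1.8, "M": 1.8,
                "A": 1.8, "D": 0.5, "E": 0.5, "K": 0.5, "R": 0.5, "P": 0.5,
                "Q": 0.5, "S": 0.5}


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class Implant:
    motif_id: str
    position: int  # 1-based start in the root
    conserved: bool = True


@dataclass(frozen=True)
class FamilyParams:
    """Study-like family conditions.

    Defaults give eight orthologs of length 800 with two long disordered
    segments, background substitution 0.2 per site, perfectly conserved
    implants (``q_motif = 0``), and no indels.
    """

    n_orthologs: int = 8
    length: int = 800
    disordered_spans: tuple[tuple[int, int], ...] = ((1, 250), (551, 800))
    implants: tuple[Implant, ...] = ()
    q_bg: float = 0.2
    q_motif: float = 0.0
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.q_bg <= 1 and 0 <= self.q_motif <= 1):
            raise SimulationError("substitution probabilities must be in [0,1]")
        for imp in self.implants:
            if imp.conserved and self.q_motif >= self.q_bg and self.q_bg > 0:
                raise SimulationError("conserved implants need q_motif < q_bg")
        if self.indel_rate != 0.0:
            raise SimulationError(
                "indels are not simulated; indel_rate must be 0"
            )
        for a, b in self.disordered_spans:
            if not (1 <= a <= b <= self.length):
                raise SimulationError(f"disordered span {a}..{b} out of bounds")


@dataclass(frozen=True)
class ImplantTruth:
    motif_id: str
    start: int
    end: int
    in_disordered_span: bool
    #: ortholog id -> pattern still matches inside the implant interval
    survived: dict[str, bool] = field(compare=False, default_factory=dict)


@dataclass(frozen=True)
class GroundTruth:
    disordered_spans: tuple[tuple[int, int], ...]
    implants: tuple[ImplantTruth, ...]


def _composition(multipliers: dict[str, float]) -> tuple[np.ndarray, list[str]]:
    letters = list(AMINO_ACIDS)
    w = np.array([SWISSPROT_COMPOSITION[a] * multipliers.get(a, 1.0) for a in letters])
    return w / w.sum(), letters


def sample_peptide(pattern: CompiledPattern, rng: np.random.Generator,
                   bg: BackgroundFrequencies | None = None) -> str:
    """Draw a peptide matching the pattern: uniform variant choice, residues
    drawn from the background restricted to each position's allowed set."""
    bg = bg or BackgroundFrequencies()
    variant = pattern.variants[rng.integers(len(pattern.variants))]
    out = []
    for residues in variant:
        letters = sorted(residues)
        p = np.array([bg[a] for a in letters])
        out.append(letters[rng.choice(len(letters), p=p / p.sum())])
    return "".join(out)


def _disrupt(peptide: str, variant_sets: Sequence[frozenset[str]],
             rng: np.random.Generator) -> str:
    """Force one position outside every allowed class of the first variant."""
    k = int(rng.integers(len(variant_sets)))
    forbidden = variant_sets[k]
    choices = sorted(set(AMINO_ACIDS) - forbidden)
    if not choices:  # fully degenerate position; try another
        for k2, residues in enumerate(variant_sets):
            choices = sorted(set(AMINO_ACIDS) - residues)
            if choices:
                k = k2
                break
        else:
            raise SimulationError("pattern matches every residue at every position")
    new = peptide[:k] + choices[int(rng.integers(len(choices)))] + peptide[k + 1 :]
    return new


def simulate_family(
    params: FamilyParams, catalog: Catalog
) -> tuple[list[ProteinRecord], MultipleAlignment, GroundTruth]:
    """Generate a family plus its trivial alignment and recomputed truth.

    The reference (``ortholog_00``) carries the implants verbatim; derived
    orthologs substitute per site (from the background distribution,
    excluding the current residue).  A non-conserved implant is disrupted
    in every derived ortholog by forcing one position outside the
    pattern's residue class.  Survival is then *recomputed* by matching
    the class pattern inside the implant interval of each emitted
    sequence.
    """
    rng = np.random.default_rng(params.seed)
    p_dis, letters = _composition(DISORDER_ENRICH)
    p_ord, _ = _composition(ORDER_ENRICH)
    is_dis = np.zeros(params.length, dtype=bool)
    for a, b in params.disordered_spans:
        is_dis[a - 1 : b] = True

    root = [
        letters[rng.choice(20, p=p_dis if is_dis[i] else p_ord)]
        for i in range(params.length)
    ]

    # implant peptides, checking bounds and overlap
    occupied = np.zeros(params.length, dtype=bool)
    spans: list[tuple[Implant, int, int, str]] = []
    for imp in params.implants:
        cls = catalog.get_class(imp.motif_id)
        peptide = sample_peptide(cls.compiled, rng)
        start, end = imp.position, imp.position + len(peptide) - 1
        if end > params.length:
            raise SimulationError(f"implant {imp.motif_id}@{imp.position} out of bounds")
        if occupied[start - 1 : end].any():
            raise SimulationError(f"implant {imp.motif_id}@{imp.position} overlaps another")
        occupied[start - 1 : end] = True
        root[start - 1 : end] = list(peptide)
        spans.append((imp, start, end, peptide))

    bg_p = np.array([SWISSPROT_COMPOSITION[a] for a in letters])
    bg_p = bg_p / bg_p.sum()

    def substitute(residue: str) -> str:
        # draw from background excluding the current residue
        idx = letters.index(residue)
        w = bg_p.copy()
        w[idx] = 0.0
        w = w / w.sum()
        return letters[rng.choice(20, p=w)]

    records: list[ProteinRecord] = []
    for k in range(params.n_orthologs):
        if k == 0:
            seq = list(root)
        else:
            seq = list(root)
            q = np.full(params.length, params.q_bg)
            for imp, start, end, _ in spans:
                q[start - 1 : end] = params.q_motif
            hits = rng.random(params.length) < q
            for i in np.flatnonzero(hits):
                seq[i] = substitute(seq[i])
            for imp, start, end, peptide in spans:
                if not imp.conserved:
                    cls = catalog.get_class(imp.motif_id)
                    variant = next(
                        v for v in cls.compiled.variants if len(v) == len(peptide)
                    )
                    broken = _disrupt("".join(seq[start - 1 : end]), variant, rng)
                    seq[start - 1 : end] = list(broken)
        records.append(ProteinRecord(id=f"ortholog_{k:02d}", species=f"sp{k:02d}",
                                     sequence="".join(seq)))

    msa = MultipleAlignment({r.id: r.sequence for r in records})

    truths = []
    for imp, start, end, _ in spans:
        cls = catalog.get_class(imp.motif_id)
        survived = {}
        for r in records:
            window = r.sequence[start - 1 : end]
            survived[r.id] = any(
                length <= len(window) - pos0
                for pos0 in range(len(window))
                for length in match_at(cls.compiled, window, pos0)
            )
        truths.append(
            ImplantTruth(
                motif_id=imp.motif_id,
                start=start,
                end=end,
                in_disordered_span=bool(is_dis[start - 1 : end].all()),
                survived=survived,
            )
        )
    truth = GroundTruth(disordered_spans=params.disordered_spans,
                        implants=tuple(truths))
    return records, msa, truth


def evaluate_recovery(
    candidates: pd.DataFrame, truth: GroundTruth, reference_id: str = "ortholog_00"
) -> dict:
    """Confusion metrics of the retained candidates against the truth.

    A retained candidate is a true positive iff it overlaps a surviving
    implant of the same class; one overlapping a non-surviving implant of
    the same class is a false positive; candidates overlapping no implant
    are spontaneous background matches ("incidental") and count as
    neither.  Recall is computed over surviving implants in disordered
    spans (the screen's targets); retained candidates on implants in
    ordered spans are reported as ``n_decoys_retained``.
    """
    retained = candidates[(candidates["retained"]) &
                          (candidates["protein_id"] == reference_id)]
    tp = fp = incidental = 0
    recovered: set[tuple[str, int]] = set()
    decoys_retained: set[tuple[str, int]] = set()
    for _, row in retained.iterrows():
        overlapping = [
            t for t in truth.implants
            if t.motif_id == row["motif_id"]
            and row["start"] <= t.end and t.start <= row["end"]
        ]
        if not overlapping:
            incidental += 1
            continue
        t = overlapping[0]
        survived = t.survived.get(reference_id, False)
        if survived and t.in_disordered_span:
            tp += 1
            recovered.add((t.motif_id, t.start))
        elif survived and not t.in_disordered_span:
            decoys_retained.add((t.motif_id, t.start))
            fp += 1
        else:
            fp += 1
    targets = [
        t for t in truth.implants
        if t.in_disordered_span and t.survived.get(reference_id, False)
    ]
    n_targets = len(targets)
    recall = (
        len({(t.motif_id, t.start) for t in targets} & recovered) / n_targets
        if n_targets else float("nan")
    )
    precision = tp / (tp + fp) if (tp + fp) else float("nan")
    return {
        "tp": tp,
        "fp": fp,
        "incidental": incidental,
        "n_targets": n_targets,
        "recall": recall,
        "precision": precision,
        "n_decoys_retained": len(decoys_retained),
    }


def default_implants(catalog: Catalog) -> tuple[Implant, ...]:
    """Six conserved implants in disordered spans and four ordered decoys,
    spread over the default segment layout."""
    return (
        Implant("lig_lir_gen1", 20, True),
        Implant("lig_14_3_3", 60, True),
        Implant("doc_pp2b_lxvp1", 110, True),
        Implant("deg_scf_fbw7", 160, True),
        Implant("lig_sh2_grb2", 600, True),
        Implant("doc_mapk", 700, True),
        # decoys in the ordered segment 251..550
        Implant("doc_pp4", 300, True),
        Implant("lig_sh2_crk_nck", 350, True),
        Implant("lig_ww3", 400, True),
        Implant("mod_gsk3_1", 450, True),
    )
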