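"""Motif scanning, background scoring and candidate selection.

The screen retains a motif hit when three conditions hold:

1. its class has a background match probability below a threshold
   (default 1e-2) or is explicitly whitelisted — modification-site classes
   and the SH3 classes are whitelisted by default because phosphosite-type
   motifs are selected on disorder propensity and annotated sites rather
   than on the probability score;
2. the hit lies inside an intrinsically disordered region (when disorder
   filtering is on);
3. the motif is conserved across enough orthologs (when a conservation
   report is available; hits with no report are retained but flagged).

The per-class score is the probability that a random position in a
background-composition sequence begins a match: the sum over fixed-length
pattern variants of the product, over pattern positions, of the background
mass of the allowed residue set.  It is an internal analogue of a published
per-motif probability, not a reproduction of any external server's score.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .catalog import Catalog, MotifClass
from .patterns import CompiledPattern, match_at
from .seqio import AMINO_ACIDS, ProteinRecord

#: UniProtKB/Swiss-Prot-like amino-acid composition (percent), normalized on load.
SWISSPROT_COMPOSITION = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.38,
    "Q": 3.93, "E": 6.72, "G": 7.07, "H": 2.27, "I": 5.91,
    "L": 9.65, "K": 5.80, "M": 2.41, "F": 3.86, "P": 4.74,
    "S": 6.63, "T": 5.35, "W": 1.10, "Y": 2.92, "V": 6.86,
}

DEFAULT_WHITELIST = frozenset(
    {"mod_ck1_1", "mod_ck2_1", "mod_gsk3_1", "lig_sh3_3_cin85", "lig_sh3_3_crk"}
)

CANDIDATE_COLUMNS = [
    "protein_id", "motif_id", "start", "end", "peptide", "site_probability",
    "in_disorder", "conserved_fraction", "retained", "reasons",
]


class BackgroundFrequencies:
    """Background residue distribution over the 20 amino acids."""

    def __init__(self, freqs: Mapping[str, float] | None = None) -> None:
        raw = dict(freqs) if freqs is not None else dict(SWISSPROT_COMPOSITION)
        missing = set(AMINO_ACIDS) - set(raw)
        if missing:
            raise ValueError(f"background missing residues {sorted(missing)}")
        if any(v <= 0 for v in raw.values()):
            raise ValueError("background frequencies must be positive")
        total = sum(raw[a] for a in AMINO_ACIDS)
        self._p = {a: raw[a] / total for a in AMINO_ACIDS}

    def __getitem__(self, residue: str) -> float:
        return self._p[residue]

    def mass(self, residues: Iterable[str]) -> float:
        return sum(self._p[a] for a in residues)

    def as_dict(self) -> dict[str, float]:
        return dict(self._p)


def uniform_background() -> BackgroundFrequencies:
    return BackgroundFrequencies({a: 1.0 for a in AMINO_ACIDS})


@dataclass(frozen=True)
class MotifMatch:
    """A scanner hit, 1-based inclusive coordinates."""

    protein_id: str
    motif_id: str
    start: int
    end: int
    peptide: str
    site_probability: float
    in_disorder: bool | None = None
    conserved_fraction: float | None = None


@dataclass(frozen=True)
class ScanConfig:
    """Candidate-selection settings (defaults follow the published screen)."""

    score_threshold: float = 1.0e-2
    require_disorder: bool = True
    conservation_min_fraction: float = 0.8
    conservation_slack_columns: int = 5
    whitelist: frozenset[str] = DEFAULT_WHITELIST

    def __post_init__(self) -> None:
        if not (0.0 < self.score_threshold < 1.0):
            raise ValueError("score_threshold must be in (0,1)")
        if not (0.0 <= self.conservation_min_fraction <= 1.0):
            raise ValueError("conservation_min_fraction must be in [0,1]")


def site_probability(
    motif: MotifClass | CompiledPattern, bg: BackgroundFrequencies
) -> float:
    """Probability that a random background position begins a pattern match."""
    compiled = motif.compiled if isinstance(motif, MotifClass) else motif
    total = 0.0
    for variant in compiled.variants:
        p = 1.0
        for residues in variant:
            p *= bg.mass(residues)
        total += p
    return total


def scan(
    record: ProteinRecord,
    motif: MotifClass,
    bg: BackgroundFrequencies | None = None,
) -> list[MotifMatch]:
    """All (possibly overlapping) matches of one class in one sequence.

    Ascending start; at equal start, shortest first.  Deterministic.
    """
    bg = bg or BackgroundFrequencies()
    prob = site_probability(motif, bg)
    seq = record.sequence
    out: list[MotifMatch] = []
    for pos0 in range(len(seq)):
        for length in match_at(motif.compiled, seq, pos0):
            out.append(
                MotifMatch(
                    protein_id=record.id,
                    motif_id=motif.motif_id,
                    start=pos0 + 1,
                    end=pos0 + length,
                    peptide=seq[pos0 : pos0 + length],
                    site_probability=prob,
                )
            )
    return out


def scan_all(
    record: ProteinRecord,
    catalog: Catalog,
    bg: BackgroundFrequencies | None = None,
) -> list[MotifMatch]:
    bg = bg or BackgroundFrequencies()
    matches: list[MotifMatch] = []
    for cls in catalog.classes:
        matches.extend(scan(record, cls, bg))
    matches.sort(key=lambda m: (m.protein_id, m.start, m.end, m.motif_id))
    return matches


def _overlaps_any(start: int, end: int, regions: Sequence[tuple[int, int]]) -> bool:
    return any(start <= b and a <= end for a, b in regions)


def select_candidates(
    matches: Sequence[MotifMatch],
    disorder_regions: Mapping[str, Sequence[tuple[int, int]]] | None,
    conservation: Mapping[tuple[str, str, int], float] | None,
    config: ScanConfig | None = None,
) -> pd.DataFrame:
    """Apply the three-stage selection; every row carries all verdicts.

    Parameters
    ----------
    matches
        Scanner output (any number of proteins/classes).
    disorder_regions
        protein_id -> list of (start, end) disordered intervals; required
        when ``config.require_disorder``.  A protein absent from the map has
        unknown disorder: its hits fail the disorder criterion rather than
        pass silently.
    conservation
        (protein_id, motif_id, start) -> conserved fraction.  Hits without
        an entry are retained but flagged ``conservation=unknown``.
    """
    config = config or ScanConfig()
    rows = []
    for m in matches:
        reasons: list[str] = []
        score_ok = (
            m.site_probability < config.score_threshold
            or m.motif_id in config.whitelist
        )
        if not score_ok:
            reasons.append(f"score {m.site_probability:.3g} >= {config.score_threshold:g}")

        if config.require_disorder:
            regions = (disorder_regions or {}).get(m.protein_id)
            in_disorder = bool(regions) and _overlaps_any(m.start, m.end, regions)
            if not in_disorder:
                reasons.append("outside disordered region")
        else:
            in_disorder = m.in_disorder if m.in_disorder is not None else True

        frac = None
        if conservation is not None:
            frac = conservation.get((m.protein_id, m.motif_id, m.start))
        if frac is None and m.conserved_fraction is not None:
            frac = m.conserved_fraction
        if frac is None:
            cons_note = "conservation=unknown"
            cons_ok = True
        else:
            cons_ok = frac >= config.conservation_min_fraction
            cons_note = ""
            if not cons_ok:
                reasons.append(
                    f"conserved fraction {frac:.2f} < {config.conservation_min_fraction:g}"
                )
        retained = score_ok and in_disorder and cons_ok
        if retained and cons_note:
            reasons.append(cons_note)
        rows.append(
            {
                "protein_id": m.protein_id,
                "motif_id": m.motif_id,
                "start": m.start,
                "end": m.end,
                "peptide": m.peptide,
                "site_probability": m.site_probability,
                "in_disorder": in_disorder,
                "conserved_fraction": float("nan") if frac is None else frac,
                "retained": retained,
                "reasons": ";".join(reasons),
            }
        )
    df = pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)
    return df.sort_values(["protein_id", "start", "end", "motif_id"]).reset_index(drop=True)


def write_candidates(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_candidates(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
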