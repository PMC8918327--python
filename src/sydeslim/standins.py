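"""Synthetic stand-in scaffolds for the SYDE study proteins.

The genuine UniProt entries (human SYDE1 Q6ZW31, human SYDE2 Q5VT97,
Drosophila Syd1 Q9V7SV) are inputs the user supplies as FASTA.  For
self-contained runs and tests, this module deterministically constructs
*synthetic* scaffold sequences that reproduce every published coordinate
fact about the real proteins:

- published motif instances implanted verbatim at their published 1-based
  starts (the one exception: the published SYDE1 MOD_CK1_1 interval
  645-651 contradicts the overlapping LIG_SH3_3 interval 641-647, so
  SPPSNRY is placed at 655 instead — see docs);
- SYDE1 length 735 with its last cysteine at 734 (the palmitoylation
  site) and both published NES candidate peptides in place;
- ordered domain blocks of the published lengths (SYDE1 C2 118 / RhoGAP
  207; SYDE2 C2 120 / RhoGAP 216) flanked by disorder-biased segments.

Everything else about the scaffolds — in particular the domain residues
themselves — is random background, NOT homologous between scaffolds.
Domain-identity figures computed on scaffolds are therefore meaningless;
those computations require the genuine sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .catalog import Catalog, load_catalog
from .seqio import ProteinRecord, RegionAnnotation
from .synthetic import DISORDER_ENRICH, ORDER_ENRICH, _composition

_BUILD_SEED = 734  # fixed so scaffold sequences are stable across runs

# adjusted placement for the internally inconsistent published interval
CK1_ADJUSTED_START = 655

_LAYOUT: dict[str, dict] = {
    "SYDE1": {
        "length": 735,
        "disorder": ((1, 269), (611, 735)),
        "C2": (270, 387),        # 118 residues
        "RhoGAP": (404, 610),    # 207 residues
    },
    "SYDE2": {
        "length": 1194,
        "disorder": ((1, 639),),
        "C2": (640, 759),        # 120 residues
        "RhoGAP": (770, 985),    # 216 residues
    },
    "DmSyd1": {
        "length": 900,
        "disorder": ((1, 350), (707, 900)),
        "C2": (360, 479),        # 120 residues
        "RhoGAP": (500, 706),    # 207 residues
    },
}

# extra literal implants beyond the motif catalog instances
_EXTRA_IMPLANTS = {
    "SYDE1": [
        (536, "LRLVSS"),            # NES candidate 536..541
        (713, "LKDFDALILDLERELS"),  # NES candidate 713..728
    ],
    "SYDE2": [
        (235, "RVLSVP"),            # validated calcineurin LxVP site
    ],
}


class StandinError(RuntimeError):
    pass


def _implants_for(protein_id: str, catalog: Catalog) -> list[tuple[int, str]]:
    out = []
    for inst in catalog.instances:
        if inst.protein_id != protein_id:
            continue
        start = inst.start
        if protein_id == "SYDE1" and inst.motif_id == "mod_ck1_1":
            start = CK1_ADJUSTED_START
        out.append((start, inst.peptide))
    out.extend(_EXTRA_IMPLANTS.get(protein_id, []))
    return sorted(out)


def _build_one(protein_id: str, catalog: Catalog, rng: np.random.Generator) -> ProteinRecord:
    layout = _LAYOUT[protein_id]
    n = layout["length"]
    p_dis, letters = _composition(DISORDER_ENRICH)
    p_ord, _ = _composition(ORDER_ENRICH)
    is_dis = np.zeros(n, dtype=bool)
    for a, b in layout["disorder"]:
        is_dis[a - 1 : b] = True
    seq = [letters[rng.choice(20, p=p_dis if is_dis[i] else p_ord)] for i in range(n)]

    implants = _implants_for(protein_id, catalog)
    protected = np.zeros(n, dtype=bool)
    for start, peptide in implants:
        end = start + len(peptide) - 1
        if end > n:
            raise StandinError(f"{protein_id}: implant @{start} exceeds length {n}")
        for k, ch in enumerate(peptide):
            i = start - 1 + k
            if protected[i] and seq[i] != ch:
                raise StandinError(
                    f"{protein_id}: overlapping implants disagree at {i + 1}"
                )
            seq[i] = ch
            protected[i] = True

    if protein_id == "SYDE1":
        seq[733] = "C"  # Cys734 palmitoylation site
        protected[733] = True
        if seq[734] == "C":
            seq[734] = "S"
        protected[734] = True
        # the palmitoylation site must be the LAST cysteine
        for i in range(610, 733):
            if seq[i] == "C" and not protected[i]:
                seq[i] = "S"

    # scrub: each implanted peptide occurs ONLY at its intended start(s)
    intended: dict[str, set[int]] = {}
    for start, peptide in implants:
        intended.setdefault(peptide, set()).add(start)
    for _round in range(100):
        text = "".join(seq)
        dirty = False
        for peptide, starts in intended.items():
            pos = text.find(peptide)
            while pos != -1:
                if pos + 1 not in starts:
                    free = [
                        i for i in range(pos, pos + len(peptide)) if not protected[i]
                    ]
                    if not free:
                        raise StandinError(
                            f"{protein_id}: cannot scrub stray {peptide!r} at {pos + 1}"
                        )
                    i = free[0]
                    seq[i] = "G" if seq[i] != "G" else "A"
                    dirty = True
                pos = text.find(peptide, pos + 1)
        if not dirty:
            break
    else:
        raise StandinError(f"{protein_id}: scrub did not converge")

    return ProteinRecord(id=protein_id, accession="", species="synthetic scaffold",
                         sequence="".join(seq))


def standin_records(catalog: Catalog | None = None) -> dict[str, ProteinRecord]:
    """The three synthetic scaffolds, keyed SYDE1 / SYDE2 / DmSyd1."""
    catalog = catalog or load_catalog()
    rng = np.random.default_rng(_BUILD_SEED)
    return {pid: _build_one(pid, catalog, rng) for pid in _LAYOUT}


def domain_boundaries() -> list[RegionAnnotation]:
    """Packaged domain-boundary table (C2 / RhoGAP per protein)."""
    out = []
    for pid, layout in _LAYOUT.items():
        for label in ("C2", "RhoGAP"):
            a, b = layout[label]
            out.append(RegionAnnotation(pid, label, a, b, source="packaged"))
    return out


def disorder_annotations() -> list[RegionAnnotation]:
    out = []
    for pid, layout in _LAYOUT.items():
        for a, b in layout["disorder"]:
            out.append(RegionAnnotation(pid, "disorder", a, b, source="packaged"))
    return out
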