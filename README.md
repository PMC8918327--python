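# sydeslim

Short-linear-motif (SLiM) discovery pipeline for the SYDE family of
C2–RhoGAP proteins (SYDE1/SYDE2 and *Drosophila* Syd1), built for
sequence-level exploration of their interaction networks in neuronal
signaling.

SYDE proteins are Rho-family GTPase-activating proteins whose long
intrinsically disordered segments harbor candidate SLiMs — 3–11-residue
patterns that dock kinases, phosphatases, adaptors and degradation
machinery.  Because short patterns match frequently by chance, a hit is
only credible when it is (i) rare under a background model, (ii) located
in a disordered region, and (iii) conserved across orthologs.  This
package implements that screen end to end, plus the domain-identity,
distance-tree and network summaries that go with it:

- a curated, validated catalog of 15 motif classes with 19 published
  SYDE1/SYDE2 instances (ELM-style classes: LIG_LIR_Gen1, LIG_SH3_3,
  LIG_14-3-3, DOC_Cyclin_RxL, DOC_MAPK, DOC_PP2B_LxvP1, DOC_PP4,
  DEG_SCF_FBW7, LIG_WW3, LIG_SH2_Grb2, LIG_SH2_Crk/Nck, MOD_CK1_1,
  MOD_CK2_1, MOD_GSK3_1);
- a scanner whose per-class score is the analytic probability that a
  random background position begins a match,
  `P = Σ_variants Π_positions Σ_{a ∈ allowed} p_bg(a)`,
  filtered at `P < 10⁻²` (modification-site classes are selected on
  disorder and annotated sites instead and ship on a whitelist);
- a fold-index disorder surrogate,
  `score = 2.785·⟨H⟩ − |⟨R⟩| − 1.151` (windowed Kyte–Doolittle
  hydropathy and net charge; negative ⇒ disordered), alongside an import
  path for external predictor output;
- ortholog conservation through multiple-alignment column mapping
  (conserved fraction over orthologs, default threshold 0.8);
- Needleman–Wunsch percent identity (BLOSUM62, affine gaps 10/0.5) for
  the C2 and RhoGAP domain comparisons;
- a neighbor-joining tree on Kimura-corrected protein distances
  `d = −ln(1 − p − 0.2p²)` with column-bootstrap supports;
- assembly of the tiered interaction network (curated low-throughput,
  high-throughput/predicted, conserved-inferred, structural-prediction
  edges) with TSV and GML export;
- a synthetic ortholog-family generator with recomputed ground truth, so
  the whole pipeline is testable without downloading anything.  The
  packaged SYDE sequences are **synthetic scaffolds** that carry the
  published coordinate facts (motif peptides at their printed positions,
  the C-terminal Cys734 palmitoylation site, domain blocks of the
  published lengths); real analyses should supply the genuine UniProt
  FASTA entries (Q6ZW31, Q5VT97, Q9V7SV).

## Worked example

Run the full pipeline on the packaged scaffolds:

```sh
sydeslim run-all --outdir out --seed 7
```

which logs `retained=155 outputs in out` — 222 raw motif matches across
the three scaffolds, 155 of which survive the probability/disorder/
conservation screen — and writes `candidates.tsv`, `identity.tsv`, the
network TSV/GML pair and a run manifest.  The network summary includes:

```
                 level                                key  count
hub-predicted-entities                              SYDE1     11
hub-predicted-entities                              SYDE2     10
```

Assembling the network from the curated predicted-interactor table alone
(`sydeslim network`) links SYDE1 to 11 distinct predicted entities and
SYDE2 to 8, with RhoA/RhoB entering as docking-derived
`structural-prediction` edges.

A self-contained synthetic experiment:

```sh
sydeslim simulate --seed 3 --out-prefix fam   # family + truth table
sydeslim scan fam.fasta --out fam_matches.tsv
```

scanning the simulated reference ortholog finds implanted sites such as
`lig_lir_gen1  20 24  DIPHV` together with incidental background
matches; feeding the family through disorder calling, conservation and
selection recovers every conserved disordered implant (recall 1.0 over
20 seeds at the default conditions) while all ordered decoys are
rejected by the disorder criterion.

## Layout

- `src/sydeslim/seqio.py` — FASTA / annotation-TSV I/O, 1-based inclusive coordinates
- `src/sydeslim/patterns.py` — restricted motif-regex grammar and expansion
- `src/sydeslim/catalog.py` + `data/motif_catalog.yaml` — motif classes, instances, validator
- `src/sydeslim/scanner.py` — scanning, background scores, candidate selection
- `src/sydeslim/disorder.py` — fold-index surrogate + interval algebra
- `src/sydeslim/conservation.py` — pairwise identity, column mapping, motif conservation
- `src/sydeslim/phylogeny.py` — distances, NJ, bootstrap, Newick
- `src/sydeslim/network.py` + `data/curated_interactions.tsv` — tiered network
- `src/sydeslim/synthetic.py` — ortholog-family generator with ground truth
- `src/sydeslim/standins.py` — synthetic SYDE scaffolds
- `src/sydeslim/pipeline.py`, `cli.py` — orchestration and the `sydeslim` CLI

See `docs/methods.md` for the underlying models, parameter choices and
known limitations.
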