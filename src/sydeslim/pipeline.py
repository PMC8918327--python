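"""End-to-end orchestration: scan -> disorder -> conservation -> selection
-> identity -> tree -> network, with a run manifest.

Each stage writes a plain-text artifact into the output directory; any
stage failure aborts the run with the stage name attached.  Given the
same configuration and seed the outputs are byte-identical.
"""

from __future__ import annotations

import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .catalog import Catalog, load_catalog, validate_catalog
from .conservation import (global_align, motif_conservation,
                           percent_identity, read_alignment)
from .disorder import (DisorderRegionSet, call_regions, foldindex_profile,
                       import_regions, merge_region_sets)
from .network import assemble, export, load_curated, summarize
from .phylogeny import bootstrap_supports, write_newick
from .scanner import (BackgroundFrequencies, ScanConfig, scan_all,
                      select_candidates, write_candidates)
from .seqio import (ProteinRecord, RegionAnnotation, extract_region,
                    read_fasta, read_region_table)
from .standins import domain_boundaries, standin_records


class PipelineError(RuntimeError):
    """A stage failed; the message is prefixed with the stage name."""


@dataclass
class PipelineConfig:
    fasta: list[str] = field(default_factory=list)  # empty -> synthetic scaffolds
    catalog_path: str | None = None
    disorder_mode: str = "surrogate"  # import | surrogate | both
    disorder_table: str | None = None
    alignments: dict[str, str] = field(default_factory=dict)  # protein_id -> aligned FASTA
    domain_table: str | None = None
    score_threshold: float = 1.0e-2
    require_disorder: bool = True
    conservation_min_fraction: float = 0.8
    conservation_slack_columns: int = 5
    outdir: str = "sydeslim_out"
    seed: int = 0
    n_bootstrap: int = 500

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"[{name}] {exc}") from exc
        return inner
    return wrap


@_stage("sequences")
def _load_sequences(config: PipelineConfig, catalog: Catalog) -> dict[str, ProteinRecord]:
    if not config.fasta:
        return standin_records(catalog)
    records: dict[str, ProteinRecord] = {}
    for path in config.fasta:
        if not Path(path).exists():
            raise FileNotFoundError(f"FASTA not found: {path}")
        for rec in read_fasta(path):
            records[rec.id] = rec
    return records


@_stage("disorder")
def _disorder(config: PipelineConfig,
              records: dict[str, ProteinRecord]) -> dict[str, DisorderRegionSet]:
    imported: dict[str, DisorderRegionSet] = {}
    if config.disorder_mode in ("import", "both"):
        if not config.disorder_table:
            raise ValueError("disorder_mode requires disorder_table")
        rows = read_region_table(config.disorder_table)
        for pid, rec in records.items():
            imported[pid] = import_regions(rows, pid, rec.length)
    out: dict[str, DisorderRegionSet] = {}
    for pid, rec in records.items():
        if config.disorder_mode == "import":
            out[pid] = imported[pid]
            continue
        surrogate = call_regions(foldindex_profile(rec))
        if config.disorder_mode == "both" and pid in imported:
            out[pid] = merge_region_sets(imported[pid], surrogate)
        else:
            out[pid] = surrogate
    return out


@_stage("conserve")
def _conservation(config: PipelineConfig, catalog: Catalog,
                  matches, records) -> dict[tuple[str, str, int], float]:
    result: dict[tuple[str, str, int], float] = {}
    for pid, aln_path in config.alignments.items():
        msa = read_alignment(aln_path)
        if pid not in msa.rows:
            raise ValueError(f"alignment {aln_path} lacks reference {pid}")
        for m in matches:
            if m.protein_id != pid:
                continue
            report = motif_conservation(
                msa, pid, m.start, m.end, catalog.get_class(m.motif_id),
                slack=config.conservation_slack_columns,
            )
            result[(pid, m.motif_id, m.start)] = report.conserved_fraction
    return result


@_stage("identity")
def _identity(records: dict[str, ProteinRecord],
              domains: list[RegionAnnotation]) -> pd.DataFrame:
    rows = []
    by_label: dict[str, list[RegionAnnotation]] = {}
    for d in domains:
        if d.protein_id in records:
            by_label.setdefault(d.label, []).append(d)
    for label, anns in sorted(by_label.items()):
        for i, a in enumerate(anns):
            for b in anns[i + 1 :]:
                seq_a = extract_region(records[a.protein_id], a)
                seq_b = extract_region(records[b.protein_id], b)
                aln = global_align(seq_a, seq_b)
                rows.append({
                    "domain": label,
                    "protein_a": a.protein_id,
                    "protein_b": b.protein_id,
                    "percent_identity": percent_identity(aln),
                    "columns": len(aln.gapped_a),
                })
    return pd.DataFrame(rows,
                        columns=["domain", "protein_a", "protein_b",
                                 "percent_identity", "columns"])


@dataclass
class RunResult:
    outdir: Path
    candidates: pd.DataFrame
    identity: pd.DataFrame
    network_summary: pd.DataFrame
    newick: str | None
    manifest: dict


def run_all(config: PipelineConfig) -> RunResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    catalog = load_catalog(config.catalog_path)
    report = validate_catalog(catalog)
    bad = [i for i in report.issues if i.check == "pattern-vs-instance"]
    if bad:
        raise PipelineError(f"[validate-catalog] {len(bad)} pattern/instance failures")

    records = _load_sequences(config, catalog)
    disorder_sets = _disorder(config, records)
    disorder_map = {pid: list(ds.intervals) for pid, ds in disorder_sets.items()}

    try:
        bg = BackgroundFrequencies()
        matches = []
        for rec in records.values():
            matches.extend(scan_all(rec, catalog, bg))
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError(f"[scan] {exc}") from exc

    conservation = _conservation(config, catalog, matches, records)

    scan_config = ScanConfig(
        score_threshold=config.score_threshold,
        require_disorder=config.require_disorder,
        conservation_min_fraction=config.conservation_min_fraction,
        conservation_slack_columns=config.conservation_slack_columns,
    )
    candidates = select_candidates(matches, disorder_map,
                                   conservation or None, scan_config)
    write_candidates(candidates, outdir / "candidates.tsv")

    domain_rows = (read_region_table(config.domain_table)
                   if config.domain_table else domain_boundaries())
    identity = _identity(records, domain_rows)
    identity.to_csv(outdir / "identity.tsv", sep="\t", index=False)

    newick = None
    for pid, aln_path in config.alignments.items():
        msa = read_alignment(aln_path)
        if len(msa.rows) >= 3:
            tree = bootstrap_supports(msa, n_replicates=config.n_bootstrap,
                                      seed=config.seed)
            newick = write_newick(tree)
            (outdir / f"tree_{pid}.nwk").write_text(newick + "\n")

    try:
        curated = load_curated()
        hub_candidates = candidates[
            candidates["protein_id"].isin(("SYDE1", "SYDE2"))
        ]
        net = assemble(curated, hub_candidates if len(hub_candidates) else None,
                       catalog)
        export(net, outdir / "network", fmt="tsv")
        export(net, outdir / "network", fmt="gml")
        net_summary = summarize(net)
        net_summary.to_csv(outdir / "network_summary.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError(f"[network] {exc}") from exc

    manifest = {
        "sydeslim_version": __version__,
        "python": sys.version.split()[0],
        "seed": config.seed,
        "config": asdict(config),
        "n_records": len(records),
        "n_matches": len(matches),
        "n_retained": int(candidates["retained"].sum()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return RunResult(outdir=outdir, candidates=candidates, identity=identity,
                     network_summary=net_summary, newick=newick, manifest=manifest)
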