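"""End-to-end orchestration: rank → sites → enrich → ddct → cellcycle.

A :class:`PipelineConfig` (usually loaded from YAML) points at the five
input files and carries the stage parameters.  :func:`run_pipeline`
executes the stages in order, writes one TSV per stage plus a consolidated
JSON report with stable key order (the timestamp is isolated in a single
field so reports are otherwise byte-reproducible), and logs seeds and
parameters.  Any stage failure aborts with the stage name and cause;
outputs of completed stages are retained.

:func:`simulate_inputs` materialises a complete synthetic input directory
(all file formats plus ``truth.json``) from a :class:`SimulationConfig`,
so the full pipeline can run without any external data.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import yaml

from . import cellcycle as cc
from . import consensus, duplex, enrichment
from . import expression as expr
from . import io as mio
from .model import canonical_mirna
from .simulate import CycleSpec, SimulationConfig, simulate_cellcycle, simulate_ct, simulate_evidence, simulate_utrs

logger = logging.getLogger("mircover")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Input paths and stage parameters for one pipeline run."""

    genes_path: str
    evidence_path: str
    mirnas_path: str
    utrs_path: str
    gmt_path: str
    ct_path: str
    reference_map_path: str
    intensities_path: str
    out_dir: str
    min_coverage: int = 2
    top_k: int = 3
    fdr_threshold: float = 0.05
    top_n_sites: int = 3
    seed: int = 0

    INPUT_FIELDS = (
        "genes_path", "evidence_path", "mirnas_path", "utrs_path",
        "gmt_path", "ct_path", "reference_map_path", "intensities_path",
    )

    def validate(self) -> None:
        for name in self.INPUT_FIELDS:
            path = Path(getattr(self, name))
            if not path.is_file():
                raise FileNotFoundError(f"{name}: no such input file: {path}")
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if not (0 < self.fdr_threshold < 1):
            raise ValueError("fdr_threshold must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**raw)


def read_reference_map(path) -> Dict[str, str]:
    df = pd.read_csv(path)
    if not {"assay", "reference"} <= set(df.columns):
        raise mio.ParseError(f"{path}: reference map needs columns assay, reference")
    return dict(zip(df["assay"], df["reference"]))


def _stage(name: str):
    def wrap(fn):
        def run(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                logger.error("stage %s: FAILED: %s", name, exc)
                raise PipelineError(name, exc) from exc
            logger.info("stage %s: done", name)
            return out
        return run
    return wrap


@_stage("rank")
def _run_rank(config: PipelineConfig, out_dir: Path):
    gene_set = mio.read_gene_set(config.genes_path)
    table = mio.read_evidence_table(config.evidence_path)
    ranked = consensus.rank_mirnas(
        table, gene_set, min_coverage=config.min_coverage, top_k=config.top_k
    )
    header = consensus.MiRNASummary.FIELDS
    mio.write_tsv([s.as_row() for s in ranked], out_dir / "ranked_mirnas.tsv", header=header)
    return gene_set, ranked


@_stage("sites")
def _run_sites(config: PipelineConfig, out_dir: Path, ranked: consensus.RankedList):
    mirnas = mio.read_fasta(config.mirnas_path, role="mirna")
    utrs = mio.read_fasta(config.utrs_path, role="utr")
    wanted = {canonical_mirna(m) for m in ranked.mirna_ids()}
    subset = {k: v for k, v in mirnas.items() if canonical_mirna(k) in wanted}
    if subset:
        mirnas = type(mirnas)(subset, role="mirna")
    hits = duplex.report_sites(mirnas, utrs, top_n=config.top_n_sites)
    mio.write_tsv(
        [
            (
                h.mirna_id, h.utr_id, h.site.start, h.site.end, h.site.site_type,
                f"{h.delta_g:.2f}",
                "|".join([h.alignment.mirna_line, h.alignment.bars, h.alignment.utr_line]),
            )
            for h in hits
        ],
        out_dir / "duplex_hits.tsv",
        header=["mirna_id", "utr_id", "start", "end", "site_type", "delta_g", "alignment"],
    )
    return hits


@_stage("enrich")
def _run_enrich(config: PipelineConfig, out_dir: Path, gene_set):
    annotation = mio.read_gmt(config.gmt_path)
    results = enrichment.enrich(gene_set, annotation, threshold=config.fdr_threshold)
    mio.write_tsv(
        [
            (r.term_id, r.count, r.term_size, r.universe_size,
             f"{r.p_value:.6g}", f"{r.fdr:.6g}", r.significant)
            for r in results
        ],
        out_dir / "enrichment.tsv",
        header=["term_id", "count", "term_size", "universe_size", "p_value", "fdr", "significant"],
    )
    return results


@_stage("ddct")
def _run_ddct(config: PipelineConfig, out_dir: Path):
    ct = expr.CtTable(
        mio.read_ct_csv(config.ct_path), read_reference_map(config.reference_map_path)
    )
    results = expr.ddct_all(ct)
    mio.write_tsv(
        [
            (r.assay, f"{r.mean_fold_change:.4f}", f"{r.p_anova:.6g}",
             f"{r.normality_p:.4g}", r.significant)
            for r in results
        ],
        out_dir / "expression.tsv",
        header=["assay", "mean_fold_change", "p_anova", "normality_p", "significant"],
    )
    return results


@_stage("cellcycle")
def _run_cellcycle(config: PipelineConfig, out_dir: Path):
    df = pd.read_csv(config.intensities_path)
    if not {"condition", "intensity"} <= set(df.columns):
        raise mio.ParseError(f"{config.intensities_path}: needs columns condition, intensity")
    has_reps = "replicate" in df.columns
    fits: Dict[str, List[cc.PhaseFractions]] = {}
    group_cols = ["condition", "replicate"] if has_reps else ["condition"]
    for key, sub in df.groupby(group_cols, sort=True):
        cond = key[0] if has_reps else (key if isinstance(key, str) else key[0])
        events = cc.IntensityEvents(str(cond), sub["intensity"].to_numpy())
        fits.setdefault(str(cond), []).append(cc.fit_phases(events))
    rows = []
    for cond in sorted(fits):
        for i, f in enumerate(fits[cond]):
            rows.append((cond, i + 1, f"{f.g0g1:.4f}", f"{f.s:.4f}", f"{f.g2m:.4f}", f.degenerate))
    mio.write_tsv(
        rows,
        out_dir / "cellcycle.tsv",
        header=["condition", "replicate", "g0g1", "s", "g2m", "degenerate"],
    )
    comparisons = None
    if len(fits) >= 2 and all(len(v) >= 3 for v in fits.values()):
        comparisons = cc.compare_conditions(fits)
    return fits, comparisons


def run_pipeline(config: PipelineConfig) -> Dict:
    """Run all stages and write ``report.json``; returns the report dict."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("pipeline start; seed=%s parameters=%s", config.seed, {
            "min_coverage": config.min_coverage, "top_k": config.top_k,
            "fdr_threshold": config.fdr_threshold, "top_n_sites": config.top_n_sites,
        })
        gene_set, ranked = _run_rank(config, out_dir)
        hits = _run_sites(config, out_dir, ranked)
        enr = _run_enrich(config, out_dir, gene_set)
        ddct = _run_ddct(config, out_dir)
        fits, comparisons = _run_cellcycle(config, out_dir)

        report = {
            "parameters": {
                "min_coverage": config.min_coverage,
                "top_k": config.top_k,
                "fdr_threshold": config.fdr_threshold,
                "top_n_sites": config.top_n_sites,
                "seed": config.seed,
            },
            "ranked_mirnas": [
                dict(zip(consensus.MiRNASummary.FIELDS, s.as_row())) for s in ranked
            ],
            "ranking_key": ranked.ranking_key,
            "duplex_hits": [
                {
                    "mirna_id": h.mirna_id, "utr_id": h.utr_id,
                    "start": h.site.start, "end": h.site.end,
                    "site_type": h.site.site_type, "delta_g": round(h.delta_g, 4),
                }
                for h in hits
            ],
            "enrichment": [
                {
                    "term_id": r.term_id, "count": r.count, "term_size": r.term_size,
                    "p_value": r.p_value, "fdr": r.fdr, "significant": r.significant,
                }
                for r in enr
            ],
            "expression": [
                {
                    "assay": r.assay, "mean_fold_change": round(r.mean_fold_change, 6),
                    "p_anova": r.p_anova, "significant": r.significant,
                }
                for r in ddct
            ],
            "cell_cycle": {
                cond: [
                    {"g0g1": round(f.g0g1, 6), "s": round(f.s, 6),
                     "g2m": round(f.g2m, 6), "degenerate": f.degenerate}
                    for f in fits[cond]
                ]
                for cond in sorted(fits)
            },
            "cell_cycle_comparisons": (
                {
                    phase: {
                        "p_anova": p,
                        "tukey": {" vs ".join(pair): pv for pair, pv in tk.items()},
                    }
                    for phase, (p, tk) in comparisons.items()
                }
                if comparisons
                else None
            ),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        with (out_dir / "report.json").open("w") as fh:
            json.dump(report, fh, indent=2)
        logger.info("pipeline complete; report at %s", out_dir / "report.json")
        return report
    finally:
        logger.removeHandler(handler)
        handler.close()


def simulate_inputs(config: SimulationConfig, out_dir) -> Dict[str, str]:
    """Write every pipeline input (plus truth.json) from the generators.

    The cell-cycle input holds two conditions (empty vector and a
    G0/G1-arrested miRNA transfection) with three replicates each; the
    annotation GMT contains one term covering the whole candidate set on a
    synthetic gene universe plus random background terms.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    import numpy as np

    paths = {
        "genes": out / "genes.txt",
        "evidence": out / "evidence.tsv",
        "mirnas": out / "mirnas.fasta",
        "utrs": out / "utrs.fasta",
        "gmt": out / "annotation.gmt",
        "ct": out / "ct.csv",
        "reference_map": out / "reference_map.csv",
        "intensities": out / "intensities.csv",
        "truth": out / "truth.json",
    }
    truth: Dict = {}

    genes = list(config.evidence.genes)
    paths["genes"].write_text("".join(f"{g}\n" for g in genes))

    table, truth["evidence"] = simulate_evidence(config)
    mio.write_evidence_table(table, paths["evidence"])

    mirnas, utrs, truth["utr_sites"] = simulate_utrs(config)
    mio.write_fasta(mirnas, paths["mirnas"])
    mio.write_fasta(utrs, paths["utrs"])

    # synthetic annotation: one term holding the full candidate set on a
    # larger universe, plus random background terms
    rng = np.random.default_rng([int(config.seed), 5])
    universe = genes + [f"BG{i:04d}" for i in range(1, 195)]
    terms = {"TERM_CANDIDATES": set(genes)}
    for t in range(1, 9):
        size = int(rng.integers(5, 40))
        terms[f"TERM_BG{t}"] = set(rng.choice(universe, size=size, replace=False))
    mio.write_gmt(terms, paths["gmt"])
    truth["annotation"] = {"enriched_term": "TERM_CANDIDATES", "universe_size": len(universe)}

    ct, truth["ct_fold_changes"] = simulate_ct(config)
    ct.data.to_csv(paths["ct"], index=False)
    pd.DataFrame(
        [{"assay": a, "reference": r} for a, r in ct.reference_map.items()]
    ).to_csv(paths["reference_map"], index=False)

    conditions = {
        "empty_vector": config.cycle.fractions,
        "mir_transfected": (0.75, 0.15, 0.10),  # planted G0/G1 arrest
    }
    rows = []
    truth["cell_cycle"] = {}
    for c_idx, (cond, fracs) in enumerate(sorted(conditions.items())):
        truth["cell_cycle"][cond] = {"fractions": fracs, "replicates": 3}
        for rep in range(1, 4):
            cfg = dataclasses.replace(
                config,
                seed=(int(config.seed) * 1000 + 10 * c_idx + rep) % (2**31),
                cycle=dataclasses.replace(config.cycle, condition=cond, fractions=tuple(fracs)),
            )
            events, _ = simulate_cellcycle(cfg)
            for v in events.intensities:
                rows.append({"condition": cond, "replicate": rep, "intensity": v})
    pd.DataFrame(rows).to_csv(paths["intensities"], index=False, float_format="%.4f")

    with paths["truth"].open("w") as fh:
        json.dump(truth, fh, indent=2)
    return {k: str(v) for k, v in paths.items()}
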