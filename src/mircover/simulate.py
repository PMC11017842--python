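"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator emulates one class of study input at realistic defaults:

* evidence tables — a few "hub" miRNAs planted with multi-gene support
  across validated and predicted sources over a six-gene candidate set
  (the shape of a consensus search over target databases), on a sparse
  background of single-target miRNAs;
* 3'UTR sequences with seed sites of chosen classes planted at recorded
  offsets for random 22-nt miRNAs;
* replicate qRT-PCR Ct tables with planted fold changes, per-well Gaussian
  noise (0.15 cycles by default) and per-sample loading offsets that the
  reference normalisation must cancel;
* PI intensity mixtures with planted phase fractions (0.60/0.25/0.15 by
  default, G1 peak at 100 with 5% CV).

All draws come from one seeded ``numpy.random.default_rng`` (PCG64) per
call, derived from ``SimulationConfig.seed`` plus a fixed per-generator
stream constant, so every output is reproducible bit-for-bit.  Every
generator returns machine-readable truth alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import (
    Direction,
    EvidenceRecord,
    EvidenceTable,
    GeneSet,
    SequenceSet,
    SourceClass,
    reverse_complement,
)
from .expression import CtTable

#: The candidate gene set used as the default simulation universe: drug-target
#: genes with clinically established relevance in prostate cancer.
CANDIDATE_GENES = ("AR", "PIK3CA", "PIK3CB", "MET", "FGFR4", "EGFR")

_VALIDATED_SOURCES = ["tarbase_v8", "mirtarbase_v8", "validated_db3", "validated_db4"]
_PREDICTED_SOURCES = [
    "mirdip", "targetscan", "pita", "mirdb", "diana_microt", "mirtar",
    "predicted_db7", "predicted_db8",
]


@dataclass(frozen=True)
class HubSpec:
    """A planted multi-target miRNA.

    ``n_records`` evidence records are distributed round-robin over
    ``coverage`` genes; a deterministic ``validated_fraction`` of them are
    validated-class, of which ``negative_rate`` are negative-direction.
    """

    mirna_id: str
    coverage: int
    validated_fraction: float = 0.6
    negative_rate: float = 0.15
    n_records: int = 16


@dataclass
class EvidenceSpec:
    n_mirnas: int = 50
    genes: Tuple[str, ...] = CANDIDATE_GENES
    hubs: Tuple[HubSpec, ...] = (
        # three hubs shaped like the study's top candidates
        HubSpec("hsa-miR-124-3p", 6, validated_fraction=9 / 15, negative_rate=2 / 9, n_records=15),
        HubSpec("hsa-miR-16-5p", 6, validated_fraction=16 / 22, negative_rate=1 / 16, n_records=22),
        HubSpec("hsa-miR-27a-3p", 5, validated_fraction=8 / 12, negative_rate=2 / 8, n_records=12),
    )
    background_evidence_prob: float = 0.6  # chance a background miRNA has any record


@dataclass
class UtrSpec:
    n_mirnas: int = 3
    n_utrs: int = 6
    utr_length: int = 500
    mirna_length: int = 22
    sites_per_type: Dict[str, int] = field(
        default_factory=lambda: {"8mer": 1, "7mer-m8": 1, "7mer-A1": 1, "6mer": 1}
    )


@dataclass
class CtSpec:
    fold_changes: Dict[str, float] = field(
        default_factory=lambda: {g: 0.4 for g in CANDIDATE_GENES}
    )
    reference_assay: str = "GAPDH"
    sigma: float = 0.15  # per-well Ct noise, cycles
    replicates: int = 3
    base_ct: float = 24.0
    reference_ct: float = 16.0
    sample_offset_sd: float = 0.3  # per-sample loading offset, cancelled by ΔCt


@dataclass
class CycleSpec:
    condition: str = "empty_vector"
    fractions: Tuple[float, float, float] = (0.60, 0.25, 0.15)
    mu1: float = 100.0
    cv: float = 0.05
    n_events: int = 10000


@dataclass
class SimulationConfig:
    """One seed plus the per-generator specifications."""

    seed: int = 0
    evidence: EvidenceSpec = field(default_factory=EvidenceSpec)
    utr: UtrSpec = field(default_factory=UtrSpec)
    ct: CtSpec = field(default_factory=CtSpec)
    cycle: CycleSpec = field(default_factory=CycleSpec)


# fixed stream constants so the generators draw from independent streams
_STREAM = {"evidence": 1, "utr": 2, "ct": 3, "cycle": 4}


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), _STREAM[stream]])


def simulate_evidence(config: SimulationConfig) -> Tuple[EvidenceTable, Dict]:
    """Evidence table with planted hubs; truth holds per-hub expected tallies."""
    spec = config.evidence
    rng = _rng(config, "evidence")
    genes = list(spec.genes)
    for hub in spec.hubs:
        if hub.coverage > len(genes):
            raise ValueError(
                f"hub {hub.mirna_id} coverage {hub.coverage} exceeds {len(genes)} genes"
            )

    records: List[EvidenceRecord] = []
    truth: Dict[str, Dict] = {"hubs": {}, "background": []}

    def add(mirna, gene, source, sclass, direction):
        records.append(
            EvidenceRecord(
                mirna, gene, source, sclass, direction,
                confidence=round(float(rng.uniform(0.5, 1.0)), 6),
            )
        )

    for hub in spec.hubs:
        covered = list(rng.permutation(genes)[: hub.coverage])
        n_validated = round(hub.validated_fraction * hub.n_records)
        n_negative = round(hub.negative_rate * n_validated)
        n_predicted = hub.n_records - n_validated
        per_gene_counts: Dict[str, Dict[str, int]] = {g: {"v": 0, "p": 0} for g in covered}
        for k in range(n_validated):
            gene = covered[k % len(covered)]
            source = _VALIDATED_SOURCES[per_gene_counts[gene]["v"] % len(_VALIDATED_SOURCES)]
            per_gene_counts[gene]["v"] += 1
            direction = Direction.NEGATIVE if k < n_negative else Direction.POSITIVE
            add(hub.mirna_id, gene, source, SourceClass.VALIDATED, direction)
        for k in range(n_predicted):
            gene = covered[k % len(covered)]
            source = _PREDICTED_SOURCES[per_gene_counts[gene]["p"] % len(_PREDICTED_SOURCES)]
            per_gene_counts[gene]["p"] += 1
            add(hub.mirna_id, gene, source, SourceClass.PREDICTED, Direction.POSITIVE)
        truth["hubs"][hub.mirna_id] = {
            "coverage": hub.coverage,
            "n_validated_genes": len({g for g, c in per_gene_counts.items() if c["v"] > 0}),
            "n_predicted_genes": len({g for g, c in per_gene_counts.items() if c["p"] > 0}),
            "positive_evidence": n_validated - n_negative,
            "negative_evidence": n_negative,
            "net_evidence": n_validated - 2 * n_negative,
        }

    n_background = config.evidence.n_mirnas - len(spec.hubs)
    for i in range(max(0, n_background)):
        mirna = f"hsa-miR-sim-{i + 1:03d}"
        if rng.uniform() >= spec.background_evidence_prob:
            continue
        gene = genes[int(rng.integers(len(genes)))]
        n_rec = int(rng.integers(1, 3))
        for k in range(n_rec):
            validated = bool(rng.uniform() < 0.3)
            pool = _VALIDATED_SOURCES if validated else _PREDICTED_SOURCES
            add(
                mirna, gene, pool[k % len(pool)],
                SourceClass.VALIDATED if validated else SourceClass.PREDICTED,
                Direction.NEGATIVE if rng.uniform() < 0.1 else Direction.POSITIVE,
            )
        truth["background"].append({"mirna_id": mirna, "gene": gene, "n_records": n_rec})

    return EvidenceTable(records), truth


_SITE_ORDER = ("8mer", "7mer-m8", "7mer-A1", "6mer")


def _plant_site(utr: List[str], mirna: str, site_type: str, start: int) -> Tuple[int, int]:
    """Write one seed site into a mutable UTR; returns its [start, end)."""
    core = reverse_complement(mirna[1:7])
    m8 = reverse_complement(mirna[7])
    not_a = "G"  # any base but A, to block an unintended A1 extension
    not_m8 = {"A": "C", "C": "A", "G": "C", "U": "C"}[m8]
    if site_type == "8mer":
        patch = m8 + core + "A"
    elif site_type == "7mer-m8":
        patch = m8 + core + not_a
    elif site_type == "7mer-A1":
        patch = not_m8 + core + "A"
    elif site_type == "6mer":
        patch = not_m8 + core + not_a
    else:
        raise ValueError(f"unknown site type {site_type!r}")
    if start + len(patch) > len(utr) or start < 0:
        raise ValueError(f"site does not fit in UTR at offset {start}")
    utr[start : start + len(patch)] = list(patch)
    # reported coordinates cover only the site proper, not the guard bases
    if site_type == "8mer":
        return start, start + 8
    if site_type == "7mer-m8":
        return start, start + 7
    if site_type == "7mer-A1":
        return start + 1, start + 8
    return start + 1, start + 7


def simulate_utrs(config: SimulationConfig) -> Tuple[SequenceSet, SequenceSet, List[Dict]]:
    """Random miRNAs and UTRs with planted seed sites at recorded offsets.

    Returns (mirnas, utrs, truth) where truth lists dicts with mirna_id,
    utr_id, start, end and site_type of every planted site.  Chance
    background sites may additionally occur and are not listed.
    """
    spec = config.utr
    rng = _rng(config, "utr")
    alphabet = np.array(list("ACGU"))

    mirnas = {
        f"mir-sim-{i + 1}": "".join(rng.choice(alphabet, size=spec.mirna_length))
        for i in range(spec.n_mirnas)
    }
    n_sites = sum(spec.sites_per_type.get(t, 0) for t in _SITE_ORDER)
    slot = 10 + 2  # site patch (<=10 nt incl. guards) plus spacing
    if n_sites * slot + 20 > spec.utr_length:
        raise ValueError(
            f"cannot fit {n_sites} planted sites into a {spec.utr_length}-nt UTR"
        )

    utrs: Dict[str, str] = {}
    truth: List[Dict] = []
    mirna_ids = list(mirnas)
    for u in range(spec.n_utrs):
        utr_id = f"utr-sim-{u + 1}"
        seq = list("".join(rng.choice(alphabet, size=spec.utr_length)))
        mirna_id = mirna_ids[u % len(mirna_ids)]
        offsets = 10 + slot * rng.permutation(n_sites)
        idx = 0
        for site_type in _SITE_ORDER:
            for _ in range(spec.sites_per_type.get(site_type, 0)):
                start, end = _plant_site(seq, mirnas[mirna_id], site_type, int(offsets[idx]))
                truth.append(
                    {
                        "mirna_id": mirna_id,
                        "utr_id": utr_id,
                        "start": start,
                        "end": end,
                        "site_type": site_type,
                    }
                )
                idx += 1
        utrs[utr_id] = "".join(seq)

    return (
        SequenceSet(mirnas, role="mirna"),
        SequenceSet(utrs, role="utr"),
        truth,
    )


def simulate_ct(config: SimulationConfig) -> Tuple[CtTable, Dict[str, float]]:
    """Replicate Ct table with planted fold changes; truth maps assay → fold."""
    spec = config.ct
    rng = _rng(config, "ct")
    rows = []
    samples = [("treated", f"T{i + 1}") for i in range(spec.replicates)] + [
        ("control", f"C{i + 1}") for i in range(spec.replicates)
    ]
    offsets = {sid: rng.normal(0.0, spec.sample_offset_sd) for _, sid in samples}
    for group, sid in samples:
        rows.append(
            {
                "sample_id": sid,
                "group": group,
                "assay": spec.reference_assay,
                "ct": spec.reference_ct + offsets[sid] + rng.normal(0.0, spec.sigma),
            }
        )
        for assay, fold in spec.fold_changes.items():
            shift = -np.log2(fold) if group == "treated" else 0.0
            rows.append(
                {
                    "sample_id": sid,
                    "group": group,
                    "assay": assay,
                    "ct": spec.base_ct + shift + offsets[sid] + rng.normal(0.0, spec.sigma),
                }
            )
    table = CtTable(
        pd.DataFrame(rows),
        reference_map={a: spec.reference_assay for a in spec.fold_changes},
    )
    return table, dict(spec.fold_changes)


def simulate_cellcycle(config: SimulationConfig):
    """PI intensities from the constrained mixture; truth holds the fractions.

    G1 events are Normal(μ1, cv·μ1), G2/M events Normal(2μ1, 2cv·μ1) and S
    events uniform DNA content between the peaks with multiplicative stain
    noise of the same CV.
    """
    from .cellcycle import IntensityEvents

    spec = config.cycle
    fractions = np.asarray(spec.fractions, dtype=float)
    if fractions.min() < 0 or abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions must be a probability vector, got {spec.fractions}")
    rng = _rng(config, "cycle")
    n1, ns, n2 = rng.multinomial(spec.n_events, fractions)
    mu1, cv = spec.mu1, spec.cv
    g1 = rng.normal(mu1, cv * mu1, n1)
    g2 = rng.normal(2 * mu1, cv * 2 * mu1, n2)
    u = rng.uniform(mu1, 2 * mu1, ns)
    s = u * (1.0 + cv * rng.standard_normal(ns))
    x = np.abs(np.concatenate([g1, s, g2]))
    rng.shuffle(x)
    events = IntensityEvents(condition=spec.condition, intensities=x)
    truth = {
        "condition": spec.condition,
        "fractions": tuple(float(f) for f in fractions),
        "mu1": mu1,
        "cv": cv,
        "n_events": int(spec.n_events),
    }
    return events, truth
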