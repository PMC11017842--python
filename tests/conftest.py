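import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from mircover.model import Direction, EvidenceRecord, EvidenceTable, GeneSet, SourceClass

GENES6 = ("AR", "PIK3CA", "PIK3CB", "MET", "FGFR4", "EGFR")


def make_table(rows):
    """Build an EvidenceTable from (mirna, gene, source, class, direction, conf) tuples."""
    return EvidenceTable(
        [
            EvidenceRecord(m, g, s, SourceClass(c), Direction(d), conf)
            for m, g, s, c, d, conf in rows
        ]
    )


def random_rows(rng, n_mirnas=10, n_genes=6, n_sources=12, n_records=200):
    """Random raw evidence rows with unique (miRNA, gene, source) keys."""
    genes = list(GENES6[:n_genes]) + [f"G{i}" for i in range(max(0, n_genes - 6))]
    keys = set()
    rows = []
    while len(rows) < n_records:
        m = f"hsa-miR-{int(rng.integers(n_mirnas))}-5p"
        g = genes[int(rng.integers(len(genes)))]
        s = f"src{int(rng.integers(n_sources))}"
        if (m.lower(), g.upper(), s) in keys:
            continue
        keys.add((m.lower(), g.upper(), s))
        rows.append(
            (
                m,
                g,
                s,
                "validated" if rng.uniform() < 0.5 else "predicted",
                "negative" if rng.uniform() < 0.2 else "positive",
                float(np.round(rng.uniform(), 6)),
            )
        )
    return rows


@pytest.fixture
def gene_set():
    return GeneSet(GENES6)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
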