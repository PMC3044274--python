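import numpy as np
import pytest

from psmreg import PSMRecord, build_graph

#: Protein membership of the five-PSM worked example: three proteins
#: A, B, C with peptides shared as below; the graph has exactly 5 edges.
TOY_SETS = [{"A"}, {"A", "C"}, {"B"}, {"B", "C"}, {"A"}]
TOY_SCORES = [2.0, 1.5, 1.0, 0.5, 3.0]

_PEPS = "ACDEFGHIKLMNPQRSTVWY"


def make_records(protein_sets, scores=None, evalues=None):
    """Build PSMRecords with distinct peptides and the given protein sets."""
    n = len(protein_sets)
    scores = scores if scores is not None else [float(i) for i in range(n)]
    out = []
    for i, (prots, score) in enumerate(zip(protein_sets, scores)):
        pep = (_PEPS[i % 20] * 2 + _PEPS[(i // 20) % 20]) * 3
        out.append(
            PSMRecord(
                psm_id=i,
                spectrum_id=f"s{i}",
                peptide=pep,
                initial_score=float(score),
                evalue=None if evalues is None else evalues[i],
                proteins=frozenset(prots),
            )
        )
    return out


def random_records(rng, n, n_proteins=None, max_membership=3):
    """Random PSM records: each peptide belongs to 1..max_membership proteins."""
    n_proteins = n_proteins or max(2, n // 3)
    sets = []
    for _ in range(n):
        k = rng.integers(1, max_membership + 1)
        accs = rng.choice(n_proteins, size=min(k, n_proteins), replace=False)
        sets.append({f"P{a}" for a in accs})
    scores = rng.normal(0, 2, size=n)
    return make_records(sets, scores)


@pytest.fixture
def toy_records():
    return make_records(TOY_SETS, TOY_SCORES)


@pytest.fixture
def toy_graph(toy_records):
    return build_graph(toy_records)
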