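"""Synthetic target-decoy search results for end-to-end testing.

The generator emulates the structure a consistency-based re-ranker
exploits: a protein database of target and decoy entries, of which only
a fraction of the targets is actually present in the sample.  Correct
PSMs draw peptides from present proteins and high scores; incorrect
PSMs draw peptides from absent targets and decoys (in equal proportion,
so the decoy rate tracks the incorrect rate) and low scores.  Peptides
are random 10-mers, so collisions are negligible and substring mapping
recovers membership exactly; a peptide may be shared into a second
protein of the same class to exercise degenerate peptides.

All randomness flows through one ``numpy`` Generator seeded from the
config, so identical configs give byte-identical output files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .evaluate import label_psms, roc_and_auc
from .io import PSMRecord, ProteinEntry, write_psm_table
from .regularize import rerank

logger = logging.getLogger(__name__)

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_PEPTIDE_LEN = 10
_LINKER_LEN = 5


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic target-decoy experiment.

    Defaults describe a small but structured benchmark: 20 target
    proteins of which half are present, 20 decoys, ~8 tryptic-sized
    peptides per protein with 10% sharing, and 400 PSMs whose scores
    come from N(3, 1) when correct and N(1, 1) when incorrect — about
    two pooled standard deviations of separation, comparable to the
    score overlap of a mid-quality search.
    """

    n_target_proteins: int = 20
    fraction_present: float = 0.5
    n_decoy_proteins: int = 20
    peptides_per_protein: int = 8
    sharing_prob: float = 0.1
    n_psms: int = 400
    frac_correct: float = 0.5
    mu_correct: float = 3.0
    sigma_correct: float = 1.0
    mu_incorrect: float = 1.0
    sigma_incorrect: float = 1.0
    seed: int = 7

    def __post_init__(self):
        for name in ("n_target_proteins", "n_decoy_proteins", "peptides_per_protein", "n_psms"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        if not 0.0 < self.fraction_present <= 1.0:
            raise ConfigError(f"fraction_present must be in (0, 1], got {self.fraction_present}")
        if not 0.0 <= self.sharing_prob < 1.0:
            raise ConfigError(f"sharing_prob must be in [0, 1), got {self.sharing_prob}")
        if not 0.0 < self.frac_correct < 1.0 and self.frac_correct != 1.0:
            raise ConfigError(f"frac_correct must be in (0, 1], got {self.frac_correct}")
        if self.sigma_correct <= 0 or self.sigma_incorrect <= 0:
            raise ConfigError("score sigmas must be positive")
        if self.n_present == 0:
            raise ConfigError("fraction_present rounds to zero present proteins")
        if self.mu_correct <= self.mu_incorrect:
            logger.warning(
                "mu_correct (%.3g) <= mu_incorrect (%.3g): benchmark has no signal",
                self.mu_correct,
                self.mu_incorrect,
            )

    @property
    def n_present(self) -> int:
        return round(self.fraction_present * self.n_target_proteins)


@dataclass(frozen=True)
class SyntheticDataset:
    """In-memory result of one generator run."""

    proteins: list[ProteinEntry]
    records: list[PSMRecord]
    is_correct: np.ndarray  # truth per record, distinct from target/decoy label
    present_accessions: frozenset[str]
    config: SyntheticConfig


def _random_peptide(rng: np.random.Generator, taken: set[str]) -> str:
    while True:
        pep = "".join(rng.choice(_AMINO_ACIDS, size=_PEPTIDE_LEN))
        if pep not in taken:
            taken.add(pep)
            return pep


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Build proteins, PSM records and the correctness truth vector."""
    rng = np.random.default_rng(config.seed)
    taken: set[str] = set()

    target_accs = [f"TP{i:04d}" for i in range(config.n_target_proteins)]
    decoy_accs = [f"DECOY_RP{i:04d}" for i in range(config.n_decoy_proteins)]

    # peptide -> protein membership, built per class so sharing stays in-class
    peptides_of: dict[str, list[str]] = {acc: [] for acc in target_accs + decoy_accs}
    membership: dict[str, set[str]] = {}
    for accs in (target_accs, decoy_accs):
        for acc in accs:
            n_pep = 1 + rng.poisson(config.peptides_per_protein - 1)
            for _ in range(n_pep):
                pep = _random_peptide(rng, taken)
                peptides_of[acc].append(pep)
                membership[pep] = {acc}
                if len(accs) > 1 and rng.random() < config.sharing_prob:
                    other = accs[rng.integers(len(accs))]
                    while other == acc:
                        other = accs[rng.integers(len(accs))]
                    peptides_of[other].append(pep)
                    membership[pep].add(other)

    proteins = []
    for acc in target_accs + decoy_accs:
        parts = []
        for pep in peptides_of[acc]:
            parts.append("".join(rng.choice(_AMINO_ACIDS, size=_LINKER_LEN)))
            parts.append(pep)
        parts.append("".join(rng.choice(_AMINO_ACIDS, size=_LINKER_LEN)))
        proteins.append(
            ProteinEntry(
                accession=acc,
                sequence="".join(parts),
                is_decoy=acc.startswith("DECOY_"),
            )
        )

    present = frozenset(rng.choice(target_accs, size=config.n_present, replace=False))
    correct_pool = sorted(p for p, accs in membership.items() if accs & present)
    absent_pool = sorted(
        p
        for p, accs in membership.items()
        if not (accs & present) and any(a in target_accs for a in accs)
    )
    decoy_pool = sorted(
        p for p, accs in membership.items() if all(a.startswith("DECOY_") for a in accs)
    )
    if not correct_pool:
        raise ConfigError("no peptides in present proteins; increase counts")

    records: list[PSMRecord] = []
    truth = np.empty(config.n_psms, dtype=bool)
    for k in range(config.n_psms):
        correct = bool(rng.random() < config.frac_correct)
        truth[k] = correct
        if correct:
            pep = correct_pool[rng.integers(len(correct_pool))]
            score = rng.normal(config.mu_correct, config.sigma_correct)
        else:
            # absent targets and decoys in equal proportion
            pool = absent_pool if (absent_pool and rng.random() < 0.5) else decoy_pool
            pep = pool[rng.integers(len(pool))]
            score = rng.normal(config.mu_incorrect, config.sigma_incorrect)
        records.append(
            PSMRecord(
                psm_id=k,
                spectrum_id=f"spec{k:05d}",
                peptide=pep,
                initial_score=float(score),
                evalue=float(10.0 ** (-score)),
                proteins=frozenset(membership[pep]),
            )
        )
    return SyntheticDataset(
        proteins=proteins,
        records=records,
        is_correct=truth,
        present_accessions=present,
        config=config,
    )


def generate_dataset(
    config: SyntheticConfig, out_dir: str | Path
) -> tuple[Path, Path, Path]:
    """Run the generator and write FASTA, PSM TSV and truth TSV files.

    Returns the three paths (proteins.fasta, psms.tsv, truth.tsv).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ds = generate(config)

    fasta_path = out_dir / "proteins.fasta"
    with open(fasta_path, "w", encoding="utf-8") as fh:
        for p in ds.proteins:
            fh.write(f">{p.accession}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i : i + 60] + "\n")

    psm_path = out_dir / "psms.tsv"
    write_psm_table(ds.records, psm_path)

    truth_path = out_dir / "truth.tsv"
    pd.DataFrame(
        {"psm_id": range(len(ds.records)), "is_correct": ds.is_correct.astype(int)}
    ).to_csv(truth_path, sep="\t", index=False)
    return fasta_path, psm_path, truth_path


@dataclass(frozen=True)
class BenchmarkResult:
    """Paired AUCs of the initial and regularized scores."""

    auc_initial: float
    auc_regularized: dict[float, float]
    n_psms: int


def benchmark_improvement(
    config: SyntheticConfig, lambdas: Sequence[float] = (0.5,)
) -> BenchmarkResult:
    """Generate one dataset, rerank at each lambda, compare AUCs.

    Labels follow the target-decoy protocol (decoy membership = false
    positive), so the comparison mirrors how a real search would be
    scored.
    """
    ds = generate(config)
    labels = label_psms(ds.records, decoy_pattern="DECOY_")
    X = np.array([r.initial_score for r in ds.records])
    auc_initial = roc_and_auc(X, labels).auc
    auc_reg = {}
    for lam in lambdas:
        _, result = rerank(ds.records, lambda_=float(lam))
        auc_reg[float(lam)] = roc_and_auc(result.Y, labels).auc
    return BenchmarkResult(
        auc_initial=auc_initial, auc_regularized=auc_reg, n_psms=len(ds.records)
    )
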