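"""Sample- and SNP-level quality control.

Pipeline order: sex-concordance filter, then per-sample missingness, then
per-SNP missingness.  All filters are idempotent and the composed filter is
re-run-stable (filtering filtered output removes nothing further).

Concordance between call sets (duplicate pairs, or panel vs reference calls)
is the fraction of *jointly non-missing* calls that agree; pairs where either
call is missing are excluded from the denominator so the statistic does not
depend on the missingness rate.  A denominator of zero yields ``nan`` (the
undefined marker), never 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import MISSING, GenotypePanel


@dataclass
class QcReport:
    """Counts and fractions from a QC pass."""

    n_input_samples: int = 0
    n_removed_sex_discordant: int = 0
    n_removed_missingness: int = 0
    n_removed_snps: int = 0
    per_snp_missing_fraction: dict[str, float] = field(default_factory=dict)
    duplicate_concordance: float = float("nan")
    reference_concordance: float = float("nan")
    removed_sample_ids: list[str] = field(default_factory=list)
    removed_locus_ids: list[str] = field(default_factory=list)

    def to_text(self) -> str:
        lines = [
            f"input samples\t{self.n_input_samples}",
            f"removed: sex discordant\t{self.n_removed_sex_discordant}",
            f"removed: sample missingness\t{self.n_removed_missingness}",
            f"removed: SNPs\t{self.n_removed_snps}",
            f"duplicate concordance\t{self.duplicate_concordance:.4f}",
            f"reference concordance\t{self.reference_concordance:.4f}",
        ]
        for lid, frac in sorted(self.per_snp_missing_fraction.items()):
            lines.append(f"snp missing fraction\t{lid}\t{frac:.4f}")
        return "\n".join(lines) + "\n"

    def to_dict(self) -> dict:
        return {
            "n_input_samples": self.n_input_samples,
            "n_removed_sex_discordant": self.n_removed_sex_discordant,
            "n_removed_missingness": self.n_removed_missingness,
            "n_removed_snps": self.n_removed_snps,
            "per_snp_missing_fraction": dict(self.per_snp_missing_fraction),
            "duplicate_concordance": self.duplicate_concordance,
            "reference_concordance": self.reference_concordance,
            "removed_sample_ids": list(self.removed_sample_ids),
            "removed_locus_ids": list(self.removed_locus_ids),
        }


def filter_sex_discordant(panel: GenotypePanel) -> tuple[GenotypePanel, list[str]]:
    """Remove samples whose reported and genotype-inferred sex disagree.

    A sample with either field ``unknown`` is treated as concordant.
    """
    rep = panel.samples["reported_sex"].to_numpy()
    gen = panel.samples["genotype_sex"].to_numpy()
    discordant = (rep != gen) & (rep != "unknown") & (gen != "unknown")
    removed = panel.samples.loc[discordant, "sample_id"].tolist()
    return panel.subset_samples(~discordant), removed


def filter_sample_missingness(
    panel: GenotypePanel, max_missing: float = 0.20
) -> tuple[GenotypePanel, list[str]]:
    """Remove samples with strictly more than ``max_missing`` missing calls."""
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError("max_missing must be in [0,1]")
    frac = panel.missing_mask().mean(axis=1)
    drop = frac > max_missing
    removed = panel.samples.loc[drop, "sample_id"].tolist()
    return panel.subset_samples(~drop), removed


def filter_snp_missingness(
    panel: GenotypePanel, max_missing: float = 0.30
) -> tuple[GenotypePanel, list[str], dict[str, float]]:
    """Remove loci with missing fraction strictly above ``max_missing``.

    Returns the filtered panel, removed locus ids, and every locus's missing
    fraction (for the QC report).
    """
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError("max_missing must be in [0,1]")
    if panel.n_samples == 0:
        frac = np.zeros(panel.n_loci)
    else:
        frac = panel.missing_mask().mean(axis=0)
    fractions = {loc.id: float(f) for loc, f in zip(panel.loci, frac)}
    drop = frac > max_missing
    if drop.all() and panel.n_loci > 0:
        raise ValueError("SNP missingness filter would remove every locus")
    removed = [loc.id for loc, d in zip(panel.loci, drop) if d]
    return panel.subset_loci(~drop), removed, fractions


def concordance(calls_a: np.ndarray, calls_b: np.ndarray) -> float:
    """Fraction of jointly non-missing calls that agree; nan if none."""
    a = np.asarray(calls_a)
    b = np.asarray(calls_b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    both = (a != MISSING) & (b != MISSING)
    n = int(both.sum())
    if n == 0:
        return float("nan")
    return float((a[both] == b[both]).sum() / n)


def duplicate_concordance(panel: GenotypePanel) -> float:
    """Genotype concordance pooled over all flagged duplicate sample pairs."""
    ids = panel.samples["sample_id"]
    index = pd.Series(np.arange(len(ids)), index=ids)
    rows_a, rows_b = [], []
    for i, dup_of in enumerate(panel.samples["duplicate_of"]):
        if dup_of is not None and not pd.isna(dup_of) and dup_of in index.index:
            rows_a.append(panel.dosages[index[dup_of]])
            rows_b.append(panel.dosages[i])
    if not rows_a:
        return float("nan")
    return concordance(np.vstack(rows_a), np.vstack(rows_b))


def run_qc(
    panel: GenotypePanel,
    max_sample_missing: float = 0.20,
    max_snp_missing: float = 0.30,
    reference_calls: np.ndarray | None = None,
    reference_sample_ids: list[str] | None = None,
) -> tuple[GenotypePanel, QcReport]:
    """Full QC pass: sex filter -> sample missingness -> SNP missingness.

    ``reference_calls`` (optional) is a dosage matrix for a subset of samples
    (rows matching ``reference_sample_ids``) from an external call set, used
    only to compute the reference-concordance figure.
    """
    report = QcReport(n_input_samples=panel.n_samples)
    report.duplicate_concordance = duplicate_concordance(panel)
    if reference_calls is not None:
        if reference_sample_ids is None:
            raise ValueError("reference_calls requires reference_sample_ids")
        index = pd.Series(
            np.arange(panel.n_samples), index=panel.samples["sample_id"]
        )
        rows = [panel.dosages[index[s]] for s in reference_sample_ids]
        report.reference_concordance = concordance(
            np.vstack(rows), np.asarray(reference_calls)
        )

    panel, removed_sex = filter_sex_discordant(panel)
    report.n_removed_sex_discordant = len(removed_sex)
    panel, removed_miss = filter_sample_missingness(panel, max_sample_missing)
    report.n_removed_missingness = len(removed_miss)
    panel, removed_snps, fractions = filter_snp_missingness(panel, max_snp_missing)
    report.n_removed_snps = len(removed_snps)
    report.per_snp_missing_fraction = fractions
    report.removed_sample_ids = removed_sex + removed_miss
    report.removed_locus_ids = removed_snps
    return panel, report
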