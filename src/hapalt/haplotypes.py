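"""Core-motif haplotype statistics and altitude correlation.

Given phased haplotypes and population metadata, this module calls the core
introgressed motif (by default the five-SNP derived configuration, the
"AGGAA" pattern), tabulates per-population core-haplotype frequencies,
correlates them with residence altitude (Spearman), builds per-locus
derived-allele frequency profiles, and applies the shared-derived-allele
filter used to nominate candidate functional variants.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import MISSING, GenotypePanel, Locus, PanelValidationError
from .phasing import HaplotypeSet


@dataclass(frozen=True)
class CoreMotif:
    """An ordered set of panel loci that must all be derived.

    ``locus_ids`` name the member loci; a haplotype carries the motif iff it
    is derived ('1') at every member locus.
    """

    locus_ids: tuple[str, ...]

    @classmethod
    def from_panel(cls, loci: Sequence[Locus]) -> "CoreMotif":
        """The panel's flagged core loci (default panel: the five-SNP motif)."""
        ids = tuple(loc.id for loc in loci if loc.core_member)
        if not ids:
            raise PanelValidationError("panel has no core_member loci")
        return cls(ids)

    def indices(self, locus_ids: Sequence[str]) -> list[int]:
        idx = []
        for lid in self.locus_ids:
            if lid not in locus_ids:
                raise PanelValidationError(
                    f"motif locus {lid!r} absent from haplotype panel"
                )
            idx.append(list(locus_ids).index(lid))
        return idx


def carries_core(haplotype: str, motif: CoreMotif,
                 locus_ids: Sequence[str]) -> bool:
    """True iff the haplotype is derived at every motif locus."""
    return all(haplotype[i] == "1" for i in motif.indices(locus_ids))


def pop_core_frequencies(
    hapset: HaplotypeSet,
    panel: GenotypePanel,
    motif: CoreMotif,
) -> pd.DataFrame:
    """Per-population core-haplotype frequency from hard pair assignments.

    Returns a frame with ``population_code``, ``altitude_m``,
    ``n_chromosomes`` (2 x retained samples), ``core_count`` and
    ``core_frequency``.  Populations with zero retained samples are omitted
    with a warning.
    """
    idx = motif.indices(hapset.locus_ids)
    cache: dict[str, bool] = {}

    def is_core(h: str) -> bool:
        if h not in cache:
            cache[h] = all(h[i] == "1" for i in idx)
        return cache[h]

    assign = hapset.assignments.merge(
        panel.samples[["sample_id", "population_code"]], on="sample_id"
    )
    rows = []
    for code in panel.populations.codes:
        sub = assign[assign["population_code"] == code]
        if sub.empty:
            warnings.warn(f"population {code}: no samples after QC; row omitted")
            continue
        core = sum(is_core(h) for h in sub["hap1"]) + sum(
            is_core(h) for h in sub["hap2"]
        )
        n_chrom = 2 * len(sub)
        rows.append(
            {
                "population_code": code,
                "altitude_m": panel.populations.altitude(code),
                "n_chromosomes": n_chrom,
                "core_count": int(core),
                "core_frequency": core / n_chrom,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["population_code", "altitude_m", "n_chromosomes",
                 "core_count", "core_frequency"],
    )


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman's rho (small n)."""
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    count = 0
    total = 0
    # correlation of rx with permuted ry; compare |rho| to observed
    rx_c = rx - rx.mean()
    denom_x = math.sqrt(np.sum(rx_c**2))
    tol = 1e-12
    abs_obs = abs(rho_obs)
    for perm in itertools.permutations(range(n)):
        ry_p = ry[list(perm)]
        ry_c = ry_p - ry_p.mean()
        denom_y = math.sqrt(np.sum(ry_c**2))
        r = float(np.dot(rx_c, ry_c) / (denom_x * denom_y))
        if abs(r) >= abs_obs - tol:
            count += 1
        total += 1
    return count / total


def altitude_correlation(
    freqs: pd.DataFrame,
    value_column: str = "core_frequency",
    exact_max_n: int = 8,
) -> tuple[float, float]:
    """Spearman rank correlation of a per-population value with altitude.

    Ties get midranks.  The p-value is two-sided: exact by exhaustive
    permutation for n <= ``exact_max_n``, otherwise the t-approximation.
    Constant altitude or constant values yield ``(nan, nan)`` with a warning.
    """
    if len(freqs) < 3:
        raise ValueError("altitude correlation requires >= 3 populations")
    alt = freqs["altitude_m"].to_numpy(dtype=float)
    val = freqs[value_column].to_numpy(dtype=float)
    if np.ptp(alt) == 0 or np.ptp(val) == 0:
        warnings.warn(
            "altitude or frequency is constant; Spearman correlation undefined"
        )
        return float("nan"), float("nan")
    rho, p_t = stats.spearmanr(alt, val)
    rho = float(rho)
    if len(freqs) <= exact_max_n:
        return rho, _spearman_exact_p(alt, val, rho)
    return rho, float(p_t)


def derived_freq_profile(
    panel: GenotypePanel,
    group_samples: Iterable[str] | None = None,
) -> np.ndarray:
    """Per-locus derived-allele frequency over non-missing calls.

    ``group_samples`` restricts to the named sample ids (default: all).
    Loci with no non-missing calls in the group get ``nan``.
    """
    if group_samples is not None:
        wanted = set(group_samples)
        mask = panel.samples["sample_id"].isin(wanted).to_numpy()
        if not mask.any():
            raise ValueError("group is empty")
        d = panel.dosages[mask]
    else:
        if panel.n_samples == 0:
            raise ValueError("group is empty")
        d = panel.dosages
    present = d != MISSING
    with np.errstate(invalid="ignore"):
        num = np.where(present, d, 0).sum(axis=0).astype(float)
        den = 2.0 * present.sum(axis=0)
        return np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)


def profile_by_group(
    panel: GenotypePanel, by: str = "population"
) -> pd.DataFrame:
    """Derived-allele frequency profiles per population or altitude class."""
    if by == "population":
        keys = panel.samples["population_code"]
    elif by == "altitude_class":
        from .datamodel import altitude_class

        keys = panel.samples["population_code"].map(
            lambda c: altitude_class(panel.populations.altitude(c))
        )
    else:
        raise ValueError("by must be 'population' or 'altitude_class'")
    rows = []
    for key in sorted(keys.unique()):
        ids = panel.samples.loc[keys == key, "sample_id"]
        prof = derived_freq_profile(panel, ids)
        rows.append({"group": key, **dict(zip(panel.locus_ids, prof))})
    return pd.DataFrame(rows)


def shared_variant_filter(
    carriers: Sequence[str],
    non_carriers: Sequence[str],
    archaic: str,
    locus_ids: Sequence[str],
) -> list[str]:
    """Loci whose derived allele is shared by the archaic genome and all
    carrier haplotypes but absent from every non-carrier haplotype.

    ``carriers`` / ``non_carriers`` are binary haplotype strings of modern
    chromosomes that do / do not carry the core motif; ``archaic`` is the
    archaic reference haplotype on the same locus index.  Returns the locus
    ids where the allele is (i) derived, (ii) carried by the archaic
    haplotype, (iii) carried by every carrier and (iv) by no non-carrier.
    """
    n = len(locus_ids)
    for h in list(carriers) + list(non_carriers) + [archaic]:
        if len(h) != n:
            raise ValueError(
                f"haplotype length {len(h)} does not match locus set ({n})"
            )
    if not carriers:
        raise ValueError("carrier set is empty")
    out = []
    for j, lid in enumerate(locus_ids):
        if archaic[j] != "1":
            continue
        if any(h[j] != "1" for h in carriers):
            continue
        if any(h[j] == "1" for h in non_carriers):
            continue
        out.append(lid)
    return out
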