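"""Per-locus marker statistics.

All statistics are computed over non-missing diploid calls only; loci with
no data raise :class:`UndefinedStatisticError` from the scalar functions,
while the table builder reports NaN for them.

Conventions:

* MAF is the frequency of the rarer allele, in [0, 0.5].
* PIC uses the Botstein closed form; for a biallelic locus
  ``PIC = 1 - p^2 - q^2 - 2 p^2 q^2`` with ceiling 0.375 at p = 0.5.
* Expected heterozygosity (genetic diversity) is ``2pq``, ceiling 0.50.
* HWE is a 1-df chi-square goodness of fit against (p^2, 2pq, q^2) with no
  continuity correction; monomorphic loci get p = 1.
"""

from __future__ import annotations

from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .variant_io import MISSING, GenotypeMatrix


class UndefinedStatisticError(ValueError):
    """Raised when a locus statistic has no defined value (e.g. all missing)."""


class ParameterError(ValueError):
    """Invalid statistic parameter (frequencies, counts, bases)."""


class SubstitutionClass(str, Enum):
    TRANSITION = "TRANSITION"
    TRANSVERSION = "TRANSVERSION"


_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def _alt_freq(calls: np.ndarray) -> float:
    calls = np.asarray(calls)
    obs = calls[calls != MISSING]
    if obs.size == 0:
        raise UndefinedStatisticError("all calls missing at locus")
    return float(obs.sum()) / (2 * obs.size)


def maf(calls: Sequence[int]) -> float:
    """Minor allele frequency from dosage-coded calls (missing ignored)."""
    p = _alt_freq(np.asarray(calls))
    return min(p, 1.0 - p)


def pic(freqs: float | Sequence[float]) -> float:
    """Polymorphism information content (Botstein form).

    Accepts either a single biallelic allele frequency ``p`` (the second is
    ``1 - p``) or a full frequency vector summing to 1.
    """
    if np.isscalar(freqs):
        p = float(freqs)  # type: ignore[arg-type]
        if not 0.0 <= p <= 1.0:
            raise ParameterError(f"allele frequency outside [0, 1]: {p}")
        f = np.array([p, 1.0 - p])
    else:
        f = np.asarray(freqs, dtype=float)
        if (f < 0).any() or (f > 1).any() or abs(f.sum() - 1.0) > 1e-9:
            raise ParameterError("frequencies must lie on the simplex")
    value = 1.0 - np.sum(f**2)
    for i in range(len(f)):
        for j in range(i + 1, len(f)):
            value -= 2.0 * f[i] ** 2 * f[j] ** 2
    return float(value)


def heterozygosity(calls: Sequence[int]) -> tuple[float, float]:
    """(observed heterozygosity, expected heterozygosity = 2pq)."""
    calls = np.asarray(calls)
    obs = calls[calls != MISSING]
    if obs.size == 0:
        raise UndefinedStatisticError("all calls missing at locus")
    het_obs = float(np.mean(obs == 1))
    p = float(obs.sum()) / (2 * obs.size)
    het_exp = 2.0 * p * (1.0 - p)
    return het_obs, het_exp


def hwe_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Hardy-Weinberg chi-square goodness-of-fit p-value (1 df).

    Expected counts are (n p^2, 2 n p q, n q^2) from the observed allele
    frequencies.  Monomorphic samples return p = 1.0 by convention so that
    downstream filters can act on them rather than crash.
    """
    counts = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    if (counts < 0).any():
        raise ParameterError("genotype counts must be non-negative")
    n = counts.sum()
    if n <= 0:
        raise ParameterError("total genotype count must be positive")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    expected = n * np.array([p**2, 2 * p * q, q**2])
    chi2 = float(np.sum((counts - expected) ** 2 / expected))
    return float(stats.chi2.sf(chi2, df=1))


def classify_substitution(ref: str, alt: str) -> SubstitutionClass:
    """Transition (A<->G, C<->T) versus transversion."""
    if ref not in "ACGT" or alt not in "ACGT" or len(ref) != 1 or len(alt) != 1:
        raise ParameterError(f"invalid bases: {ref!r}, {alt!r}")
    if ref == alt:
        raise ParameterError("ref and alt must differ")
    same_family = ({ref, alt} <= _PURINES) or ({ref, alt} <= _PYRIMIDINES)
    return SubstitutionClass.TRANSITION if same_family else SubstitutionClass.TRANSVERSION


def ts_tv_ratio(n_transitions: int, n_transversions: int) -> float:
    """Transition/transversion count ratio, rounded to 2 decimals."""
    if n_transversions <= 0:
        raise ParameterError("transversion count must be positive")
    return round(n_transitions / n_transversions, 2)


def substitution_class_counts(gm: GenotypeMatrix) -> pd.Series:
    """Counts of the six unordered substitution classes across a panel."""
    labels = ["/".join(sorted((m.ref, m.alt))) for m in gm.markers]
    return pd.Series(labels).value_counts()


def site_stats_table(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus statistics table for every marker in the matrix.

    Columns: marker, chrom, pos, maf, pic, het_obs, het_exp, hwe_p,
    missing_rate, ts_tv_class.  Loci with no data get NaN statistics.
    """
    rows = []
    for j, m in enumerate(gm.markers):
        calls = gm.dosage[:, j]
        missing_rate = float(np.mean(calls == MISSING))
        obs = calls[calls != MISSING]
        if obs.size == 0:
            stats_vals = dict(maf=np.nan, pic=np.nan, het_obs=np.nan,
                              het_exp=np.nan, hwe_p=np.nan)
        else:
            p = float(obs.sum()) / (2 * obs.size)
            het_obs, het_exp = heterozygosity(calls)
            stats_vals = dict(
                maf=min(p, 1 - p),
                pic=pic(p),
                het_obs=het_obs,
                het_exp=het_exp,
                hwe_p=hwe_test(
                    int(np.sum(obs == 0)), int(np.sum(obs == 1)), int(np.sum(obs == 2))
                ),
            )
        rows.append(
            {
                "marker": m.id,
                "chrom": m.chrom,
                "pos": m.pos,
                **stats_vals,
                "missing_rate": missing_rate,
                "ts_tv_class": classify_substitution(m.ref, m.alt).value,
            }
        )
    return pd.DataFrame(rows)
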