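"""Array multiplicity and the cas-proximal size association.

For replicons carrying exactly one cas operon, this module asks how the
size of the cas-proximal array relates to the number of arrays on the
replicon.  Two quantities are computed:

* the *largest-proximal proportion*: among single-operon replicons with a
  given array count m, the fraction whose proximal array is (inclusively)
  the largest on the replicon;
* Spearman's rank correlation, in two variants.  ``aggregated_proportion``
  correlates m against the largest-proximal proportion across the
  multiplicity curve; ``per_genome`` correlates m against the proximal
  array's spacer count across individual replicons.  Both are reported
  because the two describe different computations and the distinction
  matters: the aggregated proportion is intrinsically decreasing in m even
  for i.i.d. array sizes (the chance one particular array is the maximum
  of m falls like 1/m), whereas the per-genome variant is null when sizes
  do not depend on m.

The tie-free rank formula ``r_s = 1 - 6*sum(D_i^2) / (N(N^2-1))`` is used
when ranks are unique; with ties, the rank-average Pearson generalization
applies and the result records which path was taken.
"""
from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import ArrayRecord, IntegratedSystem

VARIANTS = ("aggregated_proportion", "per_genome")


@dataclass(frozen=True)
class GenomeArrayProfile:
    accession: str
    n_cas_operons: int
    n_arrays: int
    proximal_size: int
    max_size: int

    def __post_init__(self):
        if self.proximal_size > self.max_size:
            raise ValueError("proximal_size cannot exceed max_size")

    @property
    def proximal_is_largest(self) -> bool:
        # inclusive: a proximal array tying the maximum counts as largest
        return self.proximal_size == self.max_size


@dataclass(frozen=True)
class RhoResult:
    rho: float
    n: int
    variant: str
    tie_corrected: bool


def profile_genomes(
    systems: Sequence[IntegratedSystem],
    arrays: Sequence[ArrayRecord],
) -> List[GenomeArrayProfile]:
    """One profile per replicon carrying exactly one cas operon.

    Replicons with two or more operons are excluded — the isolation rule
    that makes "the proximal array" unambiguous.  ``max_size`` is taken
    over every (filtered) array on the replicon.
    """
    n_operons = Counter(s.accession for s in systems)
    sizes_by_acc: Dict[str, List[int]] = defaultdict(list)
    for a in arrays:
        sizes_by_acc[a.accession].append(a.n_spacers)

    profiles = []
    for s in systems:
        if n_operons[s.accession] != 1:
            continue
        sizes = sizes_by_acc[s.accession]
        profiles.append(
            GenomeArrayProfile(
                accession=s.accession,
                n_cas_operons=1,
                n_arrays=len(sizes),
                proximal_size=s.proximal_array.n_spacers,
                max_size=max(sizes),
            )
        )
    return profiles


def single_cas_fraction(operon_counts: Dict[str, int]) -> float:
    """Fraction of replicons (with >= 1 operon) carrying exactly one."""
    counts = [c for c in operon_counts.values() if c >= 1]
    if not counts:
        raise ValueError("single_cas_fraction is undefined for empty input")
    return sum(1 for c in counts if c == 1) / len(counts)


def multiplicity_curve(profiles: Sequence[GenomeArrayProfile]) -> pd.DataFrame:
    """Largest-proximal proportion by array count.

    Returns a dataframe with columns ``n_arrays``, ``n_genomes``,
    ``n_proximal_largest``, ``proportion``; array counts with no genomes
    are omitted.
    """
    tally: Dict[int, List[int]] = defaultdict(lambda: [0, 0])
    for p in profiles:
        tally[p.n_arrays][0] += 1
        tally[p.n_arrays][1] += int(p.proximal_is_largest)
    rows = [
        {
            "n_arrays": m,
            "n_genomes": n_g,
            "n_proximal_largest": n_l,
            "proportion": n_l / n_g,
        }
        for m, (n_g, n_l) in sorted(tally.items())
    ]
    return pd.DataFrame(rows, columns=["n_arrays", "n_genomes", "n_proximal_largest", "proportion"])


def spearman_rho(x, y, variant: str = "per_genome") -> RhoResult:
    """Spearman rank correlation.

    Applies the tie-free difference-of-ranks formula when all ranks are
    unique; otherwise falls back to the Pearson correlation of average
    ranks (the standard tie correction), recorded via ``tie_corrected``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    n = x.size
    if n < 3:
        raise ValueError("Spearman's rho needs at least 3 observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        # a constant variable has no monotone association with anything
        return RhoResult(rho=0.0, n=int(n), variant=variant, tie_corrected=True)
    ties = (np.unique(x).size < n) or (np.unique(y).size < n)
    if not ties:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        d2 = np.sum((rx - ry) ** 2)
        rho = 1.0 - 6.0 * d2 / (n * (n**2 - 1))
    else:
        rho = float(stats.spearmanr(x, y).statistic)
    return RhoResult(rho=float(rho), n=int(n), variant=variant, tie_corrected=ties)


def proximal_size_association(
    profiles: Sequence[GenomeArrayProfile], variant: str = "aggregated_proportion"
) -> RhoResult:
    """Spearman association between array multiplicity and proximal size.

    ``aggregated_proportion`` (the default, matching the multiplicity
    curve) correlates n_arrays with the largest-proximal proportion;
    ``per_genome`` correlates n_arrays with the proximal spacer count
    across individual single-operon replicons.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    if variant == "aggregated_proportion":
        curve = multiplicity_curve(profiles)
        return spearman_rho(
            curve["n_arrays"].to_numpy(),
            curve["proportion"].to_numpy(),
            variant=variant,
        )
    x = np.array([p.n_arrays for p in profiles], dtype=float)
    y = np.array([p.proximal_size for p in profiles], dtype=float)
    return spearman_rho(x, y, variant=variant)


def profiles_to_frame(profiles: Sequence[GenomeArrayProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "accession": p.accession,
                "n_cas_operons": p.n_cas_operons,
                "n_arrays": p.n_arrays,
                "proximal_size": p.proximal_size,
                "max_size": p.max_size,
                "proximal_is_largest": int(p.proximal_is_largest),
            }
            for p in profiles
        ],
        columns=[
            "accession",
            "n_cas_operons",
            "n_arrays",
            "proximal_size",
            "max_size",
            "proximal_is_largest",
        ],
    )
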