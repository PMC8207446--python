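"""mtDNA sequence statistics.

Haplotype collapsing, haplotype/nucleotide diversity with their classical
variances, Tajima's D and Fu's Fs with coalescent-simulation p-values,
Tamura (1992) distances with gamma rate correction, AMOVA-based Phi-ST,
haplotype-frequency FST, and Benjamini-Yekutieli FDR correction.

Conventions
-----------
* Missing data (``N``, gaps, IUPAC ambiguity codes) is handled by pairwise
  deletion in distance/diversity computations.
* Nucleotide diversity ``pi`` is reported per site.
* Monomorphic populations get D = Fs = 0 with p = 1 (undefined forms avoided).
* Neutrality-test p-values are lower-tail (fraction of simulated values at or
  below the observed one), the convention of the classical software.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from phylopop.io_formats import Alignment, FormatError, PopulationMap

__all__ = [
    "HaplotypeTable",
    "PopulationDiversity",
    "DiversitySummary",
    "DistanceMatrixSeq",
    "DivergenceResult",
    "collapse_haplotypes",
    "diversity_summary",
    "neutrality_tests",
    "tamura_gamma_distance",
    "amova_phist",
    "haplotype_fst",
    "fdr_correct",
    "tajima_d",
    "fu_fs",
]


# ---------------------------------------------------------------------------
# Haplotype collapsing


@dataclass(frozen=True)
class HaplotypeTable:
    """Unique haplotypes, their variable sites, and per-population counts."""

    haplotype_sequences: tuple[str, ...]
    variable_sites: tuple[int, ...]  # 1-based alignment positions
    counts: np.ndarray  # (n_populations, n_haplotypes)
    populations: tuple[str, ...]
    sample_ids: tuple[str, ...]  # samples retained after missing-data filter
    sample_haplotype: dict  # sample_id -> haplotype index
    sample_population: dict = field(default_factory=dict)  # sample_id -> population

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotype_sequences)


def _variable_sites(codes: np.ndarray) -> list:
    """1-based columns with >= 2 distinct unambiguous states."""
    sites = []
    for j in range(codes.shape[1]):
        col = codes[:, j]
        states = set(int(x) for x in col[col >= 0])
        if len(states) >= 2:
            sites.append(j + 1)
    return sites


def collapse_haplotypes(
    aln: Alignment, popmap: PopulationMap, max_missing_frac: float = 0.1
) -> HaplotypeTable:
    """Group identical sequences into haplotypes and count them per population.

    Samples missing more than ``max_missing_frac`` of sites are excluded.
    Sequences are considered identical when they agree at every site where
    both carry an unambiguous base; compatible sequences are merged
    transitively (union-find), with the least-missing member as the
    representative.
    """
    codes = aln.to_codes()
    keep = [
        i
        for i in range(aln.n)
        if (codes[i] < 0).mean() <= max_missing_frac and aln.sample_ids[i] in popmap.assignments
    ]
    if not keep:
        raise FormatError("no samples retained for haplotype collapsing")
    sub = codes[keep]
    ids = [aln.sample_ids[i] for i in keep]
    n = len(keep)

    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            both = (sub[i] >= 0) & (sub[j] >= 0)
            if np.all(sub[i][both] == sub[j][both]):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri

    groups: dict = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    # deterministic haplotype order: first appearance in the alignment
    ordered = sorted(groups.values(), key=lambda g: min(g))
    hap_seqs = []
    sample_hap: dict = {}
    for h, members in enumerate(ordered):
        rep = min(members, key=lambda i: ((sub[i] < 0).sum(), i))
        hap_seqs.append(aln.sequences[aln.sample_ids.index(ids[rep])])
        for i in members:
            sample_hap[ids[i]] = h

    counts = np.zeros((len(popmap.populations), len(hap_seqs)), dtype=int)
    pop_index = {p: k for k, p in enumerate(popmap.populations)}
    for sid, h in sample_hap.items():
        counts[pop_index[popmap.assignments[sid]], h] += 1

    return HaplotypeTable(
        haplotype_sequences=tuple(hap_seqs),
        variable_sites=tuple(_variable_sites(sub)),
        counts=counts,
        populations=popmap.populations,
        sample_ids=tuple(ids),
        sample_haplotype=sample_hap,
        sample_population={sid: popmap.assignments[sid] for sid in ids},
    )


# ---------------------------------------------------------------------------
# Diversity


@dataclass
class PopulationDiversity:
    population: str
    n: int
    S: int
    h: float = math.nan
    h_sd: float = math.nan
    pi: float = math.nan  # per site
    pi_sd: float = math.nan
    tajima_d: float = math.nan
    tajima_d_p: float = math.nan
    fu_fs: float = math.nan
    fu_fs_p: float = math.nan


@dataclass
class DiversitySummary:
    per_population: dict  # population -> PopulationDiversity

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for pop, d in self.per_population.items():
            rows.append(
                {
                    "population": pop,
                    "n": d.n,
                    "S": d.S,
                    "h": d.h,
                    "h_sd": d.h_sd,
                    "pi_pct": 100.0 * d.pi,
                    "pi_pct_sd": 100.0 * d.pi_sd,
                    "tajima_D": d.tajima_d,
                    "tajima_D_p": d.tajima_d_p,
                    "fu_Fs": d.fu_fs,
                    "fu_Fs_p": d.fu_fs_p,
                }
            )
        return pd.DataFrame(rows)


def haplotype_diversity(hap_counts: np.ndarray) -> tuple[float, float]:
    """Nei's unbiased haplotype diversity and its SD from haplotype counts."""
    counts = np.asarray(hap_counts, dtype=float)
    counts = counts[counts > 0]
    n = counts.sum()
    if n < 2:
        return math.nan, math.nan
    p = counts / n
    sp2 = float(np.sum(p**2))
    sp3 = float(np.sum(p**3))
    h = n / (n - 1.0) * (1.0 - sp2)
    var = 2.0 / (n * (n - 1.0)) * (2.0 * (n - 2.0) * (sp3 - sp2**2) + sp2 - sp2**2)
    return h, math.sqrt(max(var, 0.0))


def mean_pairwise_differences(codes: np.ndarray, per_site: bool = True) -> float:
    """Mean pairwise differences with pairwise deletion of missing sites."""
    n = codes.shape[0]
    if n < 2:
        return math.nan
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            both = (codes[i] >= 0) & (codes[j] >= 0)
            nb = int(both.sum())
            if nb == 0:
                continue
            d = int(np.sum(codes[i][both] != codes[j][both]))
            total += d / nb if per_site else d
    return total / (n * (n - 1) / 2)


def _pi_variance(pi: float, n: int, L: int) -> float:
    """Tajima's sampling+stochastic variance of per-site nucleotide diversity."""
    if n < 2:
        return math.nan
    return (n + 1) / (3.0 * (n - 1) * L) * pi + 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1)) * pi * pi


def diversity_summary(aln: Alignment, popmap: PopulationMap) -> DiversitySummary:
    """Per-population haplotype and nucleotide diversity (Table-1 style).

    Populations with fewer than 2 samples are flagged with NaN statistics.
    """
    codes = aln.to_codes()
    index = {sid: i for i, sid in enumerate(aln.sample_ids)}
    ht = collapse_haplotypes(aln, popmap)
    out: dict = {}
    for k, pop in enumerate(popmap.populations):
        samples = [s for s in popmap.samples_in(pop) if s in index]
        rows = [index[s] for s in samples]
        sub = codes[rows]
        n = len(rows)
        S = len(_variable_sites(sub)) if n else 0
        rec = PopulationDiversity(population=pop, n=n, S=S)
        if n >= 2:
            rec.h, rec.h_sd = haplotype_diversity(ht.counts[k])
            rec.pi = mean_pairwise_differences(sub, per_site=True)
            rec.pi_sd = math.sqrt(max(_pi_variance(rec.pi, n, aln.length), 0.0))
        out[pop] = rec
    return DiversitySummary(out)


# ---------------------------------------------------------------------------
# Neutrality tests


def _tajima_constants(n: int) -> tuple:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / (i * i) for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return a1, e1, e2


def tajima_d(S: int, pi_total: float, n: int) -> float:
    """Tajima's D from segregating sites and mean pairwise differences.

    Returns 0.0 when S == 0 (design decision; avoids the undefined form).
    """
    if n < 4 or S == 0:
        return 0.0
    a1, e1, e2 = _tajima_constants(n)
    denom = math.sqrt(e1 * S + e2 * S * (S - 1))
    return (pi_total - S / a1) / denom


def _log_stirling_first(n: int) -> list:
    """log of unsigned Stirling numbers of the first kind |s(n, k)|, k=0..n."""
    row = [1]  # n = 0
    for m in range(n):
        new = [0] * (len(row) + 1)
        for k, v in enumerate(row):
            new[k] += m * v
            new[k + 1] += v
        row = new
    return [math.log(v) if v > 0 else -math.inf for v in row]


def ewens_k_distribution(n: int, theta: float) -> np.ndarray:
    """P(K = k) for k = 1..n under the Ewens sampling formula."""
    if theta <= 0:
        out = np.zeros(n)
        out[0] = 1.0
        return out
    logs = _log_stirling_first(n)
    log_rising = sum(math.log(theta + i) for i in range(n))
    logp = np.array(
        [logs[k] + k * math.log(theta) - log_rising for k in range(1, n + 1)]
    )
    p = np.exp(logp - logp.max())
    return p / p.sum()


def fu_fs(k_obs: int, theta: float, n: int) -> float:
    """Fu's Fs from the observed number of haplotypes and theta-pi.

    Fs = ln(S'/(1-S')) with S' = P(K >= k_obs) under the Ewens formula.
    Returns 0.0 for monomorphic data (k_obs <= 1 or theta <= 0).
    """
    if k_obs <= 1 or theta <= 0 or n < 2:
        return 0.0
    p = ewens_k_distribution(n, theta)
    s_prime = float(p[k_obs - 1 :].sum())
    s_prime = min(max(s_prime, 1e-300), 1 - 1e-15)
    return math.log(s_prime / (1.0 - s_prime))


def _simulate_neutral_replicates(n: int, theta: float, n_sim: int, rng: np.random.Generator):
    """Neutral single-population coalescent replicates.

    Returns arrays of (D, Fs) computed from each simulated infinite-sites
    dataset of sample size ``n`` with theta = ``theta``.
    """
    d_out = np.empty(n_sim)
    fs_out = np.empty(n_sim)
    npairs = n * (n - 1) / 2.0
    for rep in range(n_sim):
        # Kingman coalescent: record (descendant bitmask, branch length)
        masks = [1 << i for i in range(n)]
        birth = [0.0] * n
        t = 0.0
        branches: list = []
        while len(masks) > 1:
            k = len(masks)
            t += rng.exponential(2.0 / (k * (k - 1)))
            i, j = rng.choice(k, size=2, replace=False)
            if i > j:
                i, j = j, i
            branches.append((masks[i], t - birth[i]))
            branches.append((masks[j], t - birth[j]))
            masks[i] |= masks[j]
            birth[i] = t
            del masks[j], birth[j]
        lens = np.array([b[1] for b in branches])
        total = lens.sum()
        S = rng.poisson(theta / 2.0 * total)
        if S == 0:
            d_out[rep] = 0.0
            fs_out[rep] = 0.0
            continue
        which = rng.choice(len(branches), size=S, p=lens / total)
        pi_tot = 0.0
        sigs = [0] * n
        for m_idx, b_idx in enumerate(which):
            mask = branches[b_idx][0]
            c = mask.bit_count()
            pi_tot += c * (n - c)
            for s in range(n):
                if (mask >> s) & 1:
                    sigs[s] |= 1 << m_idx
        pi_tot /= npairs
        k_hap = len(set(sigs))
        d_out[rep] = tajima_d(int(S), pi_tot, n)
        fs_out[rep] = fu_fs(k_hap, pi_tot, n)
    return d_out, fs_out


def neutrality_tests(
    aln: Alignment,
    popmap: PopulationMap,
    n_sim: int = 1000,
    rng_seed: int = 0,
    summary: DiversitySummary | None = None,
) -> DiversitySummary:
    """Tajima's D and Fu's Fs per population, with simulation p-values.

    p-values are the fraction of ``n_sim`` neutral coalescent replicates
    (conditioned on n and theta-hat-pi) with statistic <= observed.
    Monomorphic populations get D = Fs = 0 with p = 1.
    """
    if summary is None:
        summary = diversity_summary(aln, popmap)
    codes = aln.to_codes()
    index = {sid: i for i, sid in enumerate(aln.sample_ids)}
    ht = collapse_haplotypes(aln, popmap)
    rng = np.random.default_rng(rng_seed)
    for k, pop in enumerate(popmap.populations):
        rec = summary.per_population[pop]
        rows = [index[s] for s in popmap.samples_in(pop) if s in index]
        n = len(rows)
        if n < 2:
            continue
        sub = codes[rows]
        S = rec.S
        pi_tot = mean_pairwise_differences(sub, per_site=False)
        k_hap = int((ht.counts[k] > 0).sum())
        if S == 0:
            rec.tajima_d, rec.tajima_d_p = 0.0, 1.0
            rec.fu_fs, rec.fu_fs_p = 0.0, 1.0
            continue
        rec.tajima_d = tajima_d(S, pi_tot, n)
        rec.fu_fs = fu_fs(k_hap, pi_tot, n)
        d_sim, fs_sim = _simulate_neutral_replicates(n, pi_tot, n_sim, rng)
        rec.tajima_d_p = float((d_sim <= rec.tajima_d).mean())
        rec.fu_fs_p = float((fs_sim <= rec.fu_fs).mean())
    return summary


# ---------------------------------------------------------------------------
# Tamura (1992) distance with gamma correction


@dataclass(frozen=True)
class DistanceMatrixSeq:
    sample_ids: tuple[str, ...]
    matrix: np.ndarray  # (n, n), symmetric, zero diagonal; NaN = saturated pair
    method: str = "tamura"
    gamma_a: float | None = None


def _tamura_pair(ci: np.ndarray, cj: np.ndarray, gamma_a: float | None) -> float:
    both = (ci >= 0) & (cj >= 0)
    L = int(both.sum())
    if L == 0:
        return math.nan
    a, b = ci[both], cj[both]
    diff = a != b
    ssum = a + b
    transitions = diff & ((ssum == 2) | (ssum == 4))  # A<->G (0+2), C<->T (1+3)
    P = float(transitions.sum()) / L
    Q = float(diff.sum()) / L - P
    gc = float(((a == 1) | (a == 2)).mean() + ((b == 1) | (b == 2)).mean()) / 2.0
    h = 2.0 * gc * (1.0 - gc)
    arg1 = 1.0 - (P / h if h > 0 else 0.0) - Q
    arg2 = 1.0 - 2.0 * Q
    if arg1 <= 0 or arg2 <= 0:
        return math.nan
    if gamma_a is None:
        return -h * math.log(arg1) - 0.5 * (1.0 - h) * math.log(arg2)
    a_ = gamma_a
    return a_ * (h * (arg1 ** (-1.0 / a_) - 1.0) + 0.5 * (1.0 - h) * (arg2 ** (-1.0 / a_) - 1.0))


def tamura_gamma_distance(aln: Alignment, gamma_a: float | None = 0.015) -> DistanceMatrixSeq:
    """Pairwise Tamura (1992) distances with gamma rate correction.

    ``gamma_a`` is the gamma shape; ``None`` gives the uncorrected Tamura
    distance (the gamma_a -> infinity limit). Saturated pairs (logarithm
    argument <= 0) are reported as NaN with a warning. Missing sites are
    pairwise-deleted.
    """
    if gamma_a is not None and gamma_a <= 0:
        raise ValueError("gamma_a must be positive")
    codes = aln.to_codes()
    n = aln.n
    out = np.zeros((n, n))
    saturated = 0
    for i in range(n):
        for j in range(i + 1, n):
            d = _tamura_pair(codes[i], codes[j], gamma_a)
            if math.isnan(d):
                saturated += 1
            out[i, j] = out[j, i] = d
    if saturated:
        warnings.warn(f"{saturated} saturated/undefined pairwise distances reported as NaN")
    return DistanceMatrixSeq(aln.sample_ids, out, method="tamura", gamma_a=gamma_a)


def pairwise_difference_distance(aln: Alignment) -> DistanceMatrixSeq:
    """Pairwise numbers of differing sites (pairwise deletion), as used for
    molecular AMOVA on raw divergences."""
    codes = aln.to_codes()
    n = aln.n
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = (codes[i] >= 0) & (codes[j] >= 0)
            out[i, j] = out[j, i] = float(np.sum(codes[i][both] != codes[j][both]))
    return DistanceMatrixSeq(aln.sample_ids, out, method="pairwise_differences", gamma_a=None)


# ---------------------------------------------------------------------------
# AMOVA / Phi-ST


@dataclass
class DivergenceResult:
    statistic: str  # "PhiST" or "FST"
    populations: tuple[str, ...]
    overall: float
    overall_p: float
    pairwise: np.ndarray  # (npop, npop), NaN diagonal / undefined pairs
    pairwise_p: np.ndarray
    fdr_flags: np.ndarray  # boolean, same shape
    fdr_critical: float

    def pairwise_dataframe(self, decimals: int | None = 2) -> pd.DataFrame:
        mat = self.pairwise if decimals is None else np.round(self.pairwise, decimals)
        return pd.DataFrame(mat, index=self.populations, columns=self.populations)


def _amova_phi(d2: np.ndarray, groups: np.ndarray, n_groups: int) -> float:
    """Two-level AMOVA Phi-ST from a squared-distance matrix and labels."""
    N = len(groups)
    ssd_total = d2.sum() / (2.0 * N)
    ssd_within = 0.0
    sizes = np.zeros(n_groups)
    for g in range(n_groups):
        idx = np.flatnonzero(groups == g)
        sizes[g] = len(idx)
        if len(idx) >= 2:
            ssd_within += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    ssd_among = ssd_total - ssd_within
    df_within = N - n_groups
    df_among = n_groups - 1
    if df_within <= 0 or df_among <= 0:
        return math.nan
    ms_within = ssd_within / df_within
    ms_among = ssd_among / df_among
    n_prime = (N - float(np.sum(sizes**2)) / N) / df_among
    sigma_a = (ms_among - ms_within) / n_prime
    denom = sigma_a + ms_within
    if denom == 0:
        return 0.0
    return sigma_a / denom


def _permutation_p(
    d2: np.ndarray, groups: np.ndarray, n_groups: int, observed: float, n_perm: int, rng
) -> float:
    count = 0
    g = groups.copy()
    for _ in range(n_perm):
        rng.shuffle(g)
        if _amova_phi(d2, g, n_groups) >= observed - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


def _amova_from_distances(
    sample_ids, popmap: PopulationMap, d2: np.ndarray, n_perm: int, rng_seed, statistic: str
) -> DivergenceResult:
    pops = popmap.populations
    pop_index = {p: k for k, p in enumerate(pops)}
    labels = np.array([pop_index[popmap.assignments[s]] for s in sample_ids])
    npop = len(pops)
    rng = np.random.default_rng(rng_seed)

    overall = _amova_phi(d2, labels, npop)
    overall_p = _permutation_p(d2, labels, npop, overall, n_perm, rng)

    pairwise = np.full((npop, npop), np.nan)
    pairwise_p = np.full((npop, npop), np.nan)
    pair_rng = np.random.default_rng([0 if rng_seed is None else rng_seed, 1])
    for a in range(npop):
        for b in range(a + 1, npop):
            idx = np.flatnonzero((labels == a) | (labels == b))
            if (labels[idx] == a).sum() < 2 or (labels[idx] == b).sum() < 2:
                continue  # pairs with a size-1 population stay NaN
            sub = d2[np.ix_(idx, idx)]
            sub_labels = (labels[idx] == b).astype(int)
            stat = _amova_phi(sub, sub_labels, 2)
            p = _permutation_p(sub, sub_labels, 2, stat, n_perm, pair_rng)
            pairwise[a, b] = pairwise[b, a] = stat
            pairwise_p[a, b] = pairwise_p[b, a] = p

    iu = np.triu_indices(npop, k=1)
    pvals = pairwise_p[iu]
    valid = ~np.isnan(pvals)
    flags_flat = np.zeros(len(pvals), dtype=bool)
    critical = math.nan
    if valid.any():
        flags_valid, critical = fdr_correct(pvals[valid].tolist(), alpha=0.05)
        flags_flat[valid] = flags_valid
    fdr_flags = np.zeros((npop, npop), dtype=bool)
    fdr_flags[iu] = flags_flat
    fdr_flags |= fdr_flags.T

    return DivergenceResult(
        statistic=statistic,
        populations=pops,
        overall=overall,
        overall_p=overall_p,
        pairwise=pairwise,
        pairwise_p=pairwise_p,
        fdr_flags=fdr_flags,
        fdr_critical=critical,
    )


def amova_phist(
    aln: Alignment,
    popmap: PopulationMap,
    dist: DistanceMatrixSeq,
    n_perm: int = 10000,
    rng_seed: int = 0,
) -> DivergenceResult:
    """AMOVA Phi-ST (overall + pairwise) from a molecular distance matrix.

    Distance entries are used directly as squared Euclidean distances, the
    convention of molecular AMOVA on difference counts or model-corrected
    distances. NaN distances (saturated pairs) are replaced by the matrix
    maximum with a warning. p-values by permuting individuals among
    populations; pairwise flags by Benjamini-Yekutieli FDR.
    """
    if len(popmap.populations) < 2:
        raise ValueError("AMOVA needs at least 2 populations")
    order = [s for s in dist.sample_ids if s in popmap.assignments]
    index = {s: i for i, s in enumerate(dist.sample_ids)}
    rows = [index[s] for s in order]
    d2 = dist.matrix[np.ix_(rows, rows)].astype(float).copy()
    if np.isnan(d2).any():
        warnings.warn("NaN distances replaced by matrix maximum for AMOVA")
        d2[np.isnan(d2)] = np.nanmax(d2)
    return _amova_from_distances(order, popmap, d2, n_perm, rng_seed, "PhiST")


def haplotype_fst(ht: HaplotypeTable, n_perm: int = 10000, rng_seed: int = 0) -> DivergenceResult:
    """Haplotype-frequency-only FST: AMOVA with inter-haplotype distance 1
    between distinct haplotypes (overall + pairwise, permutation p-values)."""
    ids = list(ht.sample_ids)
    hap = np.array([ht.sample_haplotype[s] for s in ids])
    d2 = (hap[:, None] != hap[None, :]).astype(float)
    popmap = PopulationMap(
        {s: ht.sample_population[s] for s in ids}, ht.populations
    )
    return _amova_from_distances(ids, popmap, d2, n_perm, rng_seed, "FST")


# ---------------------------------------------------------------------------
# FDR


def fdr_correct(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Yekutieli step-up FDR under arbitrary dependence.

    Returns per-test significance flags (in input order) and the realized
    family critical value ``alpha / c(m)`` with ``c(m) = sum_{i<=m} 1/i``
    (the threshold conventionally reported alongside B-Y corrections).
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    c_m = sum(1.0 / i for i in range(1, m + 1))
    order = np.argsort(p, kind="stable")
    thresholds = np.arange(1, m + 1) * alpha / (m * c_m)
    sorted_p = p[order]
    passing = np.flatnonzero(sorted_p <= thresholds)
    flags = np.zeros(m, dtype=bool)
    if passing.size:
        k = passing.max()
        flags[order[: k + 1]] = True
    return flags, alpha / c_m
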