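"""Event-based structured coalescent simulator.

Simulates gene genealogies backward in time under event-based demographic
scenarios (ordered divergence and admixture events over a set of demes),
drops HKY+G mutations for mtDNA sequence and generalized-stepwise mutations
for microsatellites, and assembles complete synthetic study datasets that
emulate the sampling design of the source study (six populations, a
concatenated 652+377 bp maternal haploid locus, 12 diploid microsatellite
loci) under scenarios H0/H1/H2.

Times are in generations backward from the present. Deme sizes are diploid
individual counts; the per-deme pairwise coalescence rate is
``1 / (inheritance_scaler * N)`` so the maternal haploid mtDNA uses scaler
0.25 and autosomal nuclear loci use scaler 2.0.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np

from phylopop.io_formats import Alignment, GenotypeTable, PopulationMap

__all__ = [
    "DivergenceEvent",
    "AdmixtureEvent",
    "Scenario",
    "ParamSet",
    "GeneTree",
    "SyntheticDataset",
    "StudyConfig",
    "default_scenario",
    "draw_params",
    "simulate_genealogy",
    "mutate_sequence",
    "mutate_microsat",
    "make_synthetic_study",
    "STUDY_POPULATIONS",
]

STUDY_POPULATIONS = (
    "Insular",
    "Western",
    "Central",
    "EasternRanges",
    "EasternCoastal",
    "Southern",
)

#: per-population sample sizes of the emulated study design
MT_SAMPLE_SIZES = {
    "Insular": 21,
    "Western": 25,
    "Central": 9,
    "EasternRanges": 16,
    "EasternCoastal": 8,
    "Southern": 11,
}
MSAT_SAMPLE_SIZES = {
    "Insular": 24,
    "Western": 26,
    "Central": 10,
    "EasternRanges": 33,
    "EasternCoastal": 12,
    "Southern": 24,
}


# ---------------------------------------------------------------------------
# Scenario description


@dataclass(frozen=True)
class DivergenceEvent:
    """Backward in time: all lineages of ``derived`` move into ``ancestral``."""

    name: str
    derived: str
    ancestral: str
    time_prior: tuple  # (low, high) generations
    shared_time: str | None = None  # events sharing this key share one draw
    after: tuple = ()  # names of events this one must be strictly older than


@dataclass(frozen=True)
class AdmixtureEvent:
    """Backward in time: each ``recipient`` lineage moves to ``donor`` w.p. r."""

    name: str
    recipient: str
    donor: str
    time_prior: tuple
    proportion_prior: tuple
    shared_time: str | None = None
    after: tuple = ()


@dataclass(frozen=True)
class Scenario:
    scenario_id: str
    populations: tuple  # sampled demes
    events: tuple  # DivergenceEvent | AdmixtureEvent, topological order
    size_priors: dict  # deme (sampled or ancestral) -> (low, high)
    mt_rate_prior: tuple = (1e-8, 1e-6)
    msat_rate_prior: tuple = (3e-5, 5e-4)
    p_single_prior: tuple = (0.8, 1.0)
    kappa_prior: tuple = (2.0, 20.0)
    gamma_shape_prior: tuple = (0.1, 1.0)
    base_freqs: tuple = (0.27, 0.32, 0.13, 0.28)  # A C G T
    allele_bounds: tuple = (5, 55)

    def validate(self) -> None:
        demes = set(self.populations)
        for ev in self.events:
            if isinstance(ev, DivergenceEvent):
                if ev.derived not in demes:
                    raise ValueError(f"event {ev.name}: derived deme {ev.derived!r} unknown")
                demes.discard(ev.derived)
                demes.add(ev.ancestral)
            else:
                if ev.recipient not in demes or ev.donor not in demes:
                    raise ValueError(f"event {ev.name}: deme not alive at event time")
        if len(demes) != 1:
            raise ValueError(f"lineages stranded: {sorted(demes)} never reach one ancestor")
        for deme in set(self.size_priors) | demes | set(self.populations):
            if deme not in self.size_priors:
                raise ValueError(f"no size prior for deme {deme!r}")


@dataclass(frozen=True)
class ParamSet:
    """One realized draw from a scenario's priors."""

    event_times: dict  # event name -> generations
    admixture_props: dict  # event name -> proportion
    sizes: dict  # deme -> diploid size
    mt_rate: float
    kappa: float
    base_freqs: tuple
    gamma_shape: float
    msat_rate: float
    p_single: float
    allele_bounds: tuple

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


# ---------------------------------------------------------------------------
# Default study scenarios (reconstructed event topology; priors configurable)

_RECENT = (1e3, 1e5)
_SIZE = (1e2, 5e4)  # upper bound keeps synthetic He in the study's range
_GEN_TIME = 2.0  # years per generation


def _mya(lo: float, hi: float, generation_time: float) -> tuple:
    return (lo * 1e6 / generation_time, hi * 1e6 / generation_time)


def default_scenario(scenario_id: str, generation_time: float = _GEN_TIME) -> Scenario:
    """Reconstructed H0/H1/H2 event topologies.

    H0: all six demes diverge from one ancestor at a single recent time.
    H1: three regional ancestors (Insular; Mainland = Western+Central+
    EasternRanges; Southeastern = EasternCoastal+Southern) with old
    between-region splits and recent within-region splits.
    H2: H1 plus an older Southern/EasternCoastal split and recent admixture
    pulses from the Mainland into Southern and (weaker) EasternCoastal.
    """
    pops = STUDY_POPULATIONS
    if scenario_id == "H0":
        events = tuple(
            DivergenceEvent(f"t0_{p}", p, "ANC", _RECENT, shared_time="t0") for p in pops
        )
        sizes = {p: _SIZE for p in pops} | {"ANC": _SIZE}
        return Scenario("H0", pops, events, sizes)

    t_ins = _mya(1.2, 2.5, generation_time)
    t_root = _mya(1.7, 6.7, generation_time)
    if scenario_id == "H1":
        events = (
            DivergenceEvent("t_w", "Western", "MAIN", _RECENT),
            DivergenceEvent("t_e", "EasternRanges", "MAIN", _RECENT),
            DivergenceEvent("t_c", "Central", "MAIN", _RECENT),
            DivergenceEvent("t_se_ec", "EasternCoastal", "SE", _RECENT, shared_time="t_se"),
            DivergenceEvent("t_se_s", "Southern", "SE", _RECENT, shared_time="t_se"),
            DivergenceEvent("t_ins_i", "Insular", "NI", t_ins, shared_time="t_ins"),
            DivergenceEvent(
                "t_ins_m", "MAIN", "NI", t_ins, shared_time="t_ins", after=("t_w", "t_e", "t_c")
            ),
            DivergenceEvent("t_root_se", "SE", "ROOT", t_root, shared_time="t_root"),
            DivergenceEvent(
                "t_root_ni", "NI", "ROOT", t_root, shared_time="t_root", after=("t_ins_i",)
            ),
        )
        sizes = {p: _SIZE for p in pops} | {k: _SIZE for k in ("MAIN", "SE", "NI", "ROOT")}
        return Scenario("H1", pops, events, sizes)

    if scenario_id == "H2":
        t_se = _mya(0.7, 1.5, generation_time)
        adm_t = (1e3, 5e4)
        events = (
            AdmixtureEvent("adm_s", "Southern", "Central", adm_t, (0.05, 0.5)),
            AdmixtureEvent("adm_ec", "EasternCoastal", "Central", adm_t, (0.01, 0.15)),
            DivergenceEvent("t_w", "Western", "MAIN", _RECENT),
            DivergenceEvent("t_e", "EasternRanges", "MAIN", _RECENT),
            DivergenceEvent("t_c", "Central", "MAIN", _RECENT, after=("adm_s", "adm_ec")),
            DivergenceEvent("t_se_ec", "EasternCoastal", "SE", t_se, shared_time="t_se"),
            DivergenceEvent("t_se_s", "Southern", "SE", t_se, shared_time="t_se"),
            DivergenceEvent("t_ins_i", "Insular", "NI", t_ins, shared_time="t_ins"),
            DivergenceEvent(
                "t_ins_m", "MAIN", "NI", t_ins, shared_time="t_ins", after=("t_w", "t_e", "t_c")
            ),
            DivergenceEvent(
                "t_root_se", "SE", "ROOT", t_root, shared_time="t_root", after=("t_se_ec",)
            ),
            DivergenceEvent(
                "t_root_ni", "NI", "ROOT", t_root, shared_time="t_root", after=("t_ins_i",)
            ),
        )
        sizes = {p: _SIZE for p in pops} | {k: _SIZE for k in ("MAIN", "SE", "NI", "ROOT")}
        return Scenario("H2", pops, events, sizes)

    raise ValueError(f"unknown scenario id {scenario_id!r}")


# ---------------------------------------------------------------------------
# Parameter draws


def _as_rng(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


def _uniform(rng, prior) -> float:
    lo, hi = prior
    if hi < lo:
        raise ValueError(f"invalid prior {prior}")
    return float(lo) if hi == lo else float(rng.uniform(lo, hi))


def draw_params(sc: Scenario, rng_seed) -> ParamSet:
    """Independent uniform draws from the scenario priors, with rejection so
    every event is strictly older than the events in its ``after`` list."""
    sc.validate()
    rng = _as_rng(rng_seed)
    for _attempt in range(10000):
        shared: dict = {}
        times: dict = {}
        props: dict = {}
        for ev in sc.events:
            if ev.shared_time is not None:
                if ev.shared_time not in shared:
                    shared[ev.shared_time] = _uniform(rng, ev.time_prior)
                times[ev.name] = shared[ev.shared_time]
            else:
                times[ev.name] = _uniform(rng, ev.time_prior)
            if isinstance(ev, AdmixtureEvent):
                props[ev.name] = _uniform(rng, ev.proportion_prior)
        ok = all(
            all(times[ev.name] > times[other] for other in ev.after) for ev in sc.events
        )
        if ok:
            break
    else:
        raise ValueError("could not satisfy event ordering constraints (priors infeasible?)")
    sizes = {deme: _uniform(rng, prior) for deme, prior in sc.size_priors.items()}
    return ParamSet(
        event_times=times,
        admixture_props=props,
        sizes=sizes,
        mt_rate=_uniform(rng, sc.mt_rate_prior),
        kappa=_uniform(rng, sc.kappa_prior),
        base_freqs=sc.base_freqs,
        gamma_shape=_uniform(rng, sc.gamma_shape_prior),
        msat_rate=_uniform(rng, sc.msat_rate_prior),
        p_single=_uniform(rng, sc.p_single_prior),
        allele_bounds=sc.allele_bounds,
    )


# ---------------------------------------------------------------------------
# Genealogy simulation


@dataclass
class GeneTree:
    """Dated genealogy: node i's parent is ``parent[i]`` (-1 for the root),
    node times in generations, leaves are nodes 0..n_leaves-1."""

    parent: np.ndarray
    time: np.ndarray
    n_leaves: int
    leaf_demes: tuple

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node (0 for the root)."""
        out = np.zeros(self.n_nodes)
        has_parent = self.parent >= 0
        out[has_parent] = self.time[self.parent[has_parent]] - self.time[has_parent]
        return out

    def tmrca(self) -> float:
        return float(self.time[-1])


def simulate_genealogy(
    ps: ParamSet,
    sc: Scenario,
    samples_per_pop: dict,
    inheritance_scaler: float = 1.0,
    rng_seed=0,
) -> GeneTree:
    """Structured coalescent under the scenario's realized event history.

    Within each deme, pairs coalesce at rate ``1/(inheritance_scaler * N)``.
    At a divergence event all lineages of the derived deme move to the
    ancestral deme; at an admixture event each recipient lineage moves to the
    donor with the event's proportion.
    """
    rng = _as_rng(rng_seed)
    leaf_demes = []
    lineages: dict = {}
    node = 0
    for pop in sc.populations:
        k = int(samples_per_pop.get(pop, 0))
        lineages.setdefault(pop, [])
        for _ in range(k):
            lineages[pop].append(node)
            leaf_demes.append(pop)
            node += 1
    n_leaves = node
    if n_leaves < 2:
        raise ValueError("need at least 2 sampled lineages")
    total_nodes = 2 * n_leaves - 1
    parent = np.full(total_nodes, -1, dtype=np.int64)
    times = np.zeros(total_nodes)

    events = sorted(
        ((ps.event_times[ev.name], i, ev) for i, ev in enumerate(sc.events)),
        key=lambda x: (x[0], x[1]),
    )
    inv_rates = {d: 1.0 / (inheritance_scaler * ps.sizes[d]) for d in ps.sizes}

    t = 0.0
    next_node = n_leaves
    ev_idx = 0
    active = {d: lst for d, lst in lineages.items() if lst}
    n_live = sum(len(v) for v in active.values())
    # incremental per-deme coalescence rates
    rates = {
        d: len(lst) * (len(lst) - 1) / 2.0 * inv_rates[d] for d, lst in active.items()
    }
    total_rate = sum(rates.values())

    def _set_rate(d: str) -> None:
        nonlocal total_rate
        total_rate -= rates.get(d, 0.0)
        k = len(active.get(d, ()))
        rates[d] = k * (k - 1) / 2.0 * inv_rates[d]
        total_rate += rates[d]

    while n_live > 1 or ev_idx < len(events):
        t_event = events[ev_idx][0] if ev_idx < len(events) else math.inf
        wait = rng.exponential(1.0 / total_rate) if total_rate > 1e-300 else math.inf
        if t + wait >= t_event:
            if t_event is math.inf:
                raise ValueError("lineages stranded: no route to a common ancestor")
            t = t_event
            ev = events[ev_idx][2]
            ev_idx += 1
            if isinstance(ev, DivergenceEvent):
                moved = active.pop(ev.derived, [])
                active.setdefault(ev.ancestral, []).extend(moved)
                _set_rate(ev.derived)
                _set_rate(ev.ancestral)
            else:
                rec = active.get(ev.recipient, [])
                if rec:
                    r = ps.admixture_props[ev.name]
                    move = rng.random(len(rec)) < r
                    stay = [lin for lin, m in zip(rec, move) if not m]
                    go = [lin for lin, m in zip(rec, move) if m]
                    active[ev.recipient] = stay
                    if go:
                        active.setdefault(ev.donor, []).extend(go)
                    _set_rate(ev.recipient)
                    _set_rate(ev.donor)
            continue
        t += wait
        u = rng.random() * total_rate
        acc = 0.0
        deme = None
        for d, r in rates.items():
            acc += r
            if u <= acc and r > 0:
                deme = d
                break
        if deme is None:  # numerical edge: pick the deme with the largest rate
            deme = max(rates, key=rates.get)
        lst = active[deme]
        k = len(lst)
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        a, b = lst[i], lst[j]
        parent[a] = next_node
        parent[b] = next_node
        times[next_node] = t
        hi, lo = max(i, j), min(i, j)
        lst[lo] = next_node
        del lst[hi]
        next_node += 1
        n_live -= 1
        _set_rate(deme)

    return GeneTree(parent, times, n_leaves, tuple(leaf_demes))


# ---------------------------------------------------------------------------
# Sequence mutation: HKY + gamma


def hky_rate_matrix(kappa: float, freqs) -> np.ndarray:
    """HKY rate matrix (states A,C,G,T) normalized to mean rate 1."""
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (4,) or abs(freqs.sum() - 1.0) > 1e-8 or np.any(freqs <= 0):
        raise ValueError("base frequencies must be 4 positive values summing to 1")
    q = np.zeros((4, 4))
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            q[i, j] = freqs[j] * (kappa if (i, j) in transitions else 1.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mean_rate = -float(np.sum(freqs * np.diag(q)))
    return q / mean_rate


def mutate_sequence(
    tree: GeneTree,
    rate: float,
    L: int,
    kappa: float = 4.0,
    freqs=(0.25, 0.25, 0.25, 0.25),
    gamma_shape: float | None = None,
    rng_seed=0,
) -> np.ndarray:
    """Evolve an L-site sequence down the genealogy under HKY(+G).

    ``rate`` is the substitution rate per site per generation. Per-site gamma
    rate multipliers of shape ``gamma_shape`` (mean 1) are applied when
    given. The root sequence is drawn from the stationary frequencies.
    Returns an (n_leaves, L) int8 matrix of states A=0 C=1 G=2 T=3.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    rng = _as_rng(rng_seed)
    q = hky_rate_matrix(kappa, freqs)
    vals, vecs = np.linalg.eig(q)
    vals = vals.real
    U = vecs.real
    V = np.linalg.inv(U)

    site_rates = (
        rng.gamma(gamma_shape, 1.0 / gamma_shape, size=L)
        if gamma_shape is not None
        else np.ones(L)
    )
    states = np.empty((tree.n_nodes, L), dtype=np.int8)
    root = tree.n_nodes - 1
    states[root] = rng.choice(4, size=L, p=np.asarray(freqs, dtype=float))
    if rate == 0:
        for node in range(tree.n_nodes - 2, -1, -1):
            states[node] = states[tree.parent[node]]
        return states[: tree.n_leaves]

    blen = tree.branch_lengths()
    # parents always have higher node index than children by construction
    for node in range(tree.n_nodes - 2, -1, -1):
        par = states[tree.parent[node]]
        tau = rate * blen[node] * site_rates  # expected substitutions per site
        e = np.exp(np.outer(tau, vals))  # (L, 4)
        probs = np.einsum("lk,kj->lj", e * U[par, :], V)
        np.clip(probs, 0.0, None, out=probs)
        probs /= probs.sum(axis=1, keepdims=True)
        u = rng.random(L)
        states[node] = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
    return states[: tree.n_leaves]


def codes_to_alignment(codes: np.ndarray, sample_ids, locus_label: str = "") -> Alignment:
    """Turn an (n, L) state matrix into an :class:`Alignment`."""
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    raw = lut[codes.astype(np.intp)]
    seqs = tuple(row.tobytes().decode("ascii") for row in raw)
    return Alignment(tuple(sample_ids), seqs, locus_label)


# ---------------------------------------------------------------------------
# Microsatellite mutation: generalized stepwise


def mutate_microsat(
    tree: GeneTree,
    rate: float,
    p_single: float = 0.9,
    bounds: tuple = (5, 55),
    geom_q: float = 0.5,
    rng_seed=0,
) -> np.ndarray:
    """Generalized stepwise mutation along the genealogy.

    Mutations are Poisson on branches; each step is +/-1 with probability
    ``p_single``, otherwise +/- (1 + Geometric(geom_q)). Allele sizes are
    reflected into ``bounds`` by folding. Returns per-leaf allele sizes.
    """
    lo, hi = bounds
    if hi - lo < 1:
        raise ValueError("allele-size bounds must span at least 2 states")
    if rate < 0:
        raise ValueError("rate must be non-negative")
    rng = _as_rng(rng_seed)
    blen = tree.branch_lengths()
    n_mut = rng.poisson(rate * blen)
    deltas = np.zeros(tree.n_nodes)
    total = int(n_mut.sum())
    if total:
        owner = np.repeat(np.arange(tree.n_nodes), n_mut)
        signs = rng.choice([-1.0, 1.0], size=total)
        steps = np.ones(total)
        if p_single < 1.0:
            multi = rng.random(total) >= p_single
            if multi.any():
                steps[multi] = 1.0 + rng.geometric(geom_q, size=int(multi.sum()))
        np.add.at(deltas, owner, signs * steps)

    values = np.zeros(tree.n_nodes)
    root = tree.n_nodes - 1
    values[root] = (lo + hi) / 2.0
    for node in range(tree.n_nodes - 2, -1, -1):
        values[node] = values[tree.parent[node]] + deltas[node]

    # reflect into [lo, hi] by folding the unbounded walk
    width = hi - lo
    y = np.mod(values[: tree.n_leaves] - lo, 2.0 * width)
    y = np.where(y > width, 2.0 * width - y, y)
    return np.rint(lo + y).astype(int)


# ---------------------------------------------------------------------------
# Full synthetic study


@dataclass(frozen=True)
class StudyConfig:
    mt_sample_sizes: dict = field(default_factory=lambda: dict(MT_SAMPLE_SIZES))
    msat_sample_sizes: dict = field(default_factory=lambda: dict(MSAT_SAMPLE_SIZES))
    seq_lengths: tuple = (652, 377)  # COI, Control Region (one genealogy)
    n_msat_loci: int = 12
    generation_time: float = _GEN_TIME
    mt_inheritance_scaler: float = 0.25
    nuclear_inheritance_scaler: float = 2.0


@dataclass
class SyntheticDataset:
    scenario_id: str
    seed: int
    params: ParamSet
    alignment: Alignment  # concatenated mtDNA, haploid
    aln_popmap: PopulationMap
    genotypes: GenotypeTable
    gt_popmap: PopulationMap
    config: StudyConfig = field(default_factory=StudyConfig)
    mt_codes: np.ndarray | None = None  # cached alignment state matrix


def make_synthetic_study(
    scenario_id: str, seed: int, config: StudyConfig | None = None
) -> SyntheticDataset:
    """Generate one complete synthetic dataset under a study scenario.

    Fully reproducible from ``(scenario_id, seed)``: one root RNG stream is
    spawned into independent sub-streams for parameter draws, the mtDNA
    locus, and each microsatellite locus. COI and the Control Region share a
    single non-recombining genealogy.
    """
    config = config or StudyConfig()
    sc = default_scenario(scenario_id, config.generation_time)
    ss = np.random.SeedSequence([zlib.crc32(scenario_id.encode()), seed])
    children = ss.spawn(2 + config.n_msat_loci)
    param_rng = np.random.default_rng(children[0])
    ps = draw_params(sc, param_rng)

    # mtDNA: one genealogy for the concatenated locus
    mt_rng = np.random.default_rng(children[1])
    mt_tree = simulate_genealogy(
        ps, sc, config.mt_sample_sizes, config.mt_inheritance_scaler, mt_rng
    )
    L = sum(config.seq_lengths)
    codes = mutate_sequence(
        mt_tree,
        ps.mt_rate,
        L,
        kappa=ps.kappa,
        freqs=ps.base_freqs,
        gamma_shape=ps.gamma_shape,
        rng_seed=mt_rng,
    )
    mt_ids = []
    mt_pairs = []
    for pop in sc.populations:
        for i in range(config.mt_sample_sizes.get(pop, 0)):
            sid = f"{pop}_mt{i + 1:02d}"
            mt_ids.append(sid)
            mt_pairs.append((sid, pop))
    alignment = codes_to_alignment(codes, mt_ids, "COI+CR")
    aln_popmap = PopulationMap.from_pairs(mt_pairs)

    # microsatellites: independent genealogies, 2 gene copies per individual
    gene_samples = {p: 2 * n for p, n in config.msat_sample_sizes.items()}
    gt_ids = []
    gt_pairs = []
    for pop in sc.populations:
        for i in range(config.msat_sample_sizes.get(pop, 0)):
            sid = f"{pop}_{i + 1:02d}"
            gt_ids.append(sid)
            gt_pairs.append((sid, pop))
    n_ind = len(gt_ids)
    calls = np.zeros((n_ind, config.n_msat_loci, 2), dtype=np.int32)
    for locus in range(config.n_msat_loci):
        rng = np.random.default_rng(children[2 + locus])
        tree = simulate_genealogy(
            ps, sc, gene_samples, config.nuclear_inheritance_scaler, rng
        )
        alleles = mutate_microsat(
            tree, ps.msat_rate, ps.p_single, ps.allele_bounds, rng_seed=rng
        )
        # consecutive gene copies pair into diploid individuals
        calls[:, locus, 0] = alleles[0::2]
        calls[:, locus, 1] = alleles[1::2]
    genotypes = GenotypeTable(
        tuple(gt_ids), tuple(f"L{j + 1:02d}" for j in range(config.n_msat_loci)), calls
    )
    gt_popmap = PopulationMap.from_pairs(gt_pairs)

    return SyntheticDataset(
        scenario_id=scenario_id,
        seed=seed,
        params=ps,
        alignment=alignment,
        aln_popmap=aln_popmap,
        genotypes=genotypes,
        gt_popmap=gt_popmap,
        config=config,
        mt_codes=codes,
    )
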