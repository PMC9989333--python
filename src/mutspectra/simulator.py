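"""Structured-coalescent simulation of context-dependent variation.

The engine draws sample genealogies backward in time under a
:class:`~mutspectra.demography.PopulationModel` (piecewise/exponential sizes,
population splits, lineage migration), then sprinkles mutations onto
branches at context-specific per-site rates and returns a
:class:`~mutspectra.variants.VariantTable` of biallelic sites.  Under
neutrality this is distributionally equivalent to a forward Wright-Fisher
simulation of the same model; a small-N forward oracle
(:func:`forward_wf_oracle`) exists to check exactly that equivalence.

Recombination is approximated by cutting the sequence into independent
non-recombining windows (default 10 kb): between-window recombination is
overstated and within-window recombination ignored, which leaves spectrum
means untouched and only approximates their variances.

Conventions: N counts diploid individuals, so a lineage pair coalesces at
rate 1/(2N) per generation; mutation counts per (branch, site) are Poisson
with mean branch length x site rate; sites struck more than once on a
genealogy are discarded (the biallelic restriction of the analysis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .demography import Epoch, PopulationModel, validate
from .mutation_model import MutationRateMatrix, _DERIVED_CODE
from .sequence import AncestralSequence
from .variants import VariantTable

__all__ = [
    "Genealogy",
    "CoalescenceError",
    "simulate_genealogy",
    "place_mutations",
    "forward_wf_oracle",
    "simulate_dataset",
]

DEFAULT_WINDOW_LENGTH = 10_000

#: Size guard for the forward Wright-Fisher oracle.
WF_MAX_N = 500


class CoalescenceError(RuntimeError):
    """The model's lineages cannot all find a common ancestor."""


@dataclass
class Genealogy:
    """A sampled genealogy.  Nodes 0..n-1 are leaves (time 0), the rest are
    coalescences in increasing time order; ``parent[root] == -1``.

    ``segments[i]`` lists ``(t0, t1, population)`` intervals covering node
    i's branch from its own time up to its parent's time, recording which
    population the lineage occupied when (needed for population-specific
    mutation matrices)."""

    parent: np.ndarray
    time: np.ndarray
    leaf_population: list
    sample_index: dict
    segments: list

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_population)

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @property
    def tmrca(self) -> float:
        return float(self.time.max())

    def branch_length(self, node: int) -> float:
        p = self.parent[node]
        return float(self.time[p] - self.time[node]) if p >= 0 else 0.0

    @property
    def total_branch_length(self) -> float:
        p = self.parent
        ok = p >= 0
        return float(np.sum(self.time[p[ok]] - self.time[np.flatnonzero(ok)]))

    def children(self) -> list:
        kids: list = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                kids[p].append(i)
        return kids

    def descendant_leaves(self, node: int, _children: Optional[list] = None) -> np.ndarray:
        kids = _children if _children is not None else self.children()
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if v < self.n_leaves:
                out.append(v)
            else:
                stack.extend(kids[v])
        return np.array(sorted(out), dtype=np.int32)


def _coalescence_wait(C: float, epoch: Epoch, t: float, u: float) -> float:
    """Time to the next coalescence among C pairs starting at t within an
    epoch, from the exponential quantile u ~ Exp(1); inf if the integrated
    hazard never reaches u (possible when sizes grow into the past)."""
    g = epoch.growth_rate
    N0 = epoch.population_size
    if g == 0.0:
        return u * 2.0 * N0 / C
    # N(s) = N0 e^{-g (s - e0)}  =>  rate(s) = C e^{g (s - e0)} / (2 N0)
    base = math.exp(g * (t - epoch.start_time))
    arg = base + u * 2.0 * N0 * g / C
    if arg <= 0.0:
        return math.inf
    return math.log(arg) / g - (t - epoch.start_time)


def simulate_genealogy(
    model: PopulationModel,
    samples: Mapping[str, int],
    seed=None,
) -> Genealogy:
    """Draw one genealogy for ``samples`` haplotypes per population.

    Backward in time: within each population, any lineage pair coalesces at
    rate 1/(2N(t)); migration relocates single lineages; at a split time all
    of the child population's lineages move into the parent.  Deterministic
    given ``seed``.
    """
    problems = validate(model)
    if problems:
        raise ValueError("invalid model: " + "; ".join(problems))
    samples = {p: int(n) for p, n in samples.items() if int(n) > 0}
    for pop in samples:
        model.population(pop)  # raises KeyError on unknown population
    n_total = sum(samples.values())
    if n_total < 2:
        raise ValueError("need at least two sampled haplotypes in total")

    rng = np.random.default_rng(seed)
    pop_order = [p.id for p in model.populations]
    pops = {pid: model.population(pid) for pid in pop_order}

    # node storage (leaves first, grouped by population in model order)
    leaf_population: list = []
    sample_index: dict = {}
    next_id = 0
    lineages: dict = {pid: [] for pid in pop_order}
    for pid in pop_order:
        n = samples.get(pid, 0)
        if n:
            ids = list(range(next_id, next_id + n))
            sample_index[pid] = np.array(ids, dtype=np.int32)
            lineages[pid].extend(ids)
            leaf_population.extend([pid] * n)
            next_id += n

    times = [0.0] * n_total
    parent = [-1] * n_total
    segments: list = [[] for _ in range(n_total)]
    open_seg: dict = {}
    for pid in pop_order:
        for node in lineages[pid]:
            open_seg[node] = (0.0, pid)

    def close_segment(node: int, t: float) -> None:
        t0, pid = open_seg.pop(node)
        if t > t0:
            segments[node].append((t0, t, pid))

    def move(node: int, t: float, dest: str) -> None:
        close_segment(node, t)
        open_seg[node] = (t, dest)

    # scheduled deterministic times: splits, epoch starts, migration bounds
    sched = {s.time for s in model.splits}
    for pid in pop_order:
        sched.update(e.start_time for e in pops[pid].epochs if e.start_time > 0)
    for m in model.migrations:
        lo, hi = m.active_interval
        if lo > 0:
            sched.add(lo)
        if math.isfinite(hi):
            sched.add(hi)
    schedule = sorted(sched)
    splits_at: dict = {}
    for s in model.splits:
        splits_at.setdefault(s.time, []).append(s)

    t = 0.0
    alive = n_total
    while alive > 1:
        ts = next((x for x in schedule if x > t), math.inf)

        best_w = math.inf
        best_event = None  # ("coal", pid) | ("mig", route)
        for pid in pop_order:
            k = len(lineages[pid])
            if k < 2:
                continue
            C = k * (k - 1) / 2.0
            w = _coalescence_wait(C, pops[pid].epoch_at(t), t, rng.exponential())
            if w < best_w:
                best_w, best_event = w, ("coal", pid)
        active_routes = [
            (m, len(lineages[m.source]) * m.rate)
            for m in model.migrations
            if m.active_at(t) and lineages[m.source]
        ]
        total_mig = sum(r for _, r in active_routes)
        if total_mig > 0:
            w = rng.exponential(1.0 / total_mig)
            if w < best_w:
                best_w, best_event = w, ("mig", active_routes)

        if t + best_w < ts:
            t += best_w
            kind, payload = best_event
            if kind == "coal":
                pid = payload
                pool = lineages[pid]
                i, j = rng.choice(len(pool), size=2, replace=False)
                a, b = pool[int(i)], pool[int(j)]
                node = len(times)
                times.append(t)
                parent.append(-1)
                segments.append([])
                parent[a] = parent[b] = node
                close_segment(a, t)
                close_segment(b, t)
                pool.remove(a)
                pool.remove(b)
                pool.append(node)
                open_seg[node] = (t, pid)
                alive -= 1
            else:
                weights = np.array([r for _, r in payload])
                route = payload[int(rng.choice(len(payload), p=weights / weights.sum()))][0]
                pool = lineages[route.source]
                node = pool.pop(int(rng.integers(len(pool))))
                lineages[route.dest].append(node)
                move(node, t, route.dest)
        else:
            if math.isinf(ts):
                raise CoalescenceError(
                    "lineages in disconnected populations cannot coalesce "
                    "(no further splits, migration or coalescence possible)"
                )
            t = ts
            for s in splits_at.get(ts, []):
                for node in lineages[s.child_population]:
                    move(node, t, s.parent_population)
                lineages[s.parent_population].extend(lineages[s.child_population])
                lineages[s.child_population] = []
            # epoch / migration boundaries need no state change

    root = next(pid for pid in pop_order if lineages[pid])
    open_seg.pop(lineages[root][0])  # root has no branch above it
    return Genealogy(
        parent=np.array(parent, dtype=np.int64),
        time=np.array(times, dtype=float),
        leaf_population=leaf_population,
        sample_index=sample_index,
        segments=segments,
    )


# ---------------------------------------------------------------------------
# mutation placement


def _resolve_matrices(matrix, populations) -> dict:
    if isinstance(matrix, MutationRateMatrix):
        table = {pid: matrix for pid in populations}
    else:
        table = dict(matrix)
        missing = [p for p in populations if p not in table]
        if missing:
            raise ValueError(f"no mutation matrix for populations {missing}")
    for pid, m in table.items():
        if not m.normalized:
            raise ValueError(
                f"matrix for {pid!r} is not normalized; call normalize_overall_rate first"
            )
    return table


def place_mutations(
    genealogy: Genealogy,
    seq: AncestralSequence,
    matrix: Union[MutationRateMatrix, Mapping[str, MutationRateMatrix]],
    seed=None,
    window: Optional[tuple] = None,
) -> VariantTable:
    """Place context-dependent mutations on a genealogy over a sequence
    window and return the biallelic variants.

    ``matrix`` may be a single normalized matrix, or one per population —
    in that case a branch segment mutates under the matrix of the population
    the lineage occupied during that segment (how a population-specific rate
    shift enters the simulation).  Sites hit more than once on the genealogy
    are discarded.
    """
    rng = np.random.default_rng(seed)
    lo, hi = window if window is not None else (0, len(seq))
    if not (0 <= lo < hi <= len(seq)):
        raise ValueError(f"bad window {window} for sequence of length {len(seq)}")
    # interior sites only: each needs both neighbours inside the full sequence
    site_lo, site_hi = max(lo, 1), min(hi, len(seq) - 1)
    tri_all = seq.triplet_codes()
    tri = tri_all[site_lo - 1 : site_hi - 1]

    # flatten branch segments
    seg_node, seg_len, seg_pop = [], [], []
    for node, segs in enumerate(genealogy.segments):
        for (t0, t1, pid) in segs:
            seg_node.append(node)
            seg_len.append(t1 - t0)
            seg_pop.append(pid)
    pops_present = sorted(set(seg_pop))
    matrices = _resolve_matrices(matrix, pops_present)

    hap_offsets = _hap_offsets(genealogy)
    if not seg_node or tri.size == 0:
        return VariantTable.from_carriers([], [], [], [], hap_offsets)

    # per-population site-rate tables on this window
    site_rates = {pid: matrices[pid].triplet_totals[tri] for pid in pops_present}
    site_cum = {pid: np.cumsum(r) for pid, r in site_rates.items()}
    pop_total = {pid: float(c[-1]) for pid, c in site_cum.items()}
    cond_cum = {pid: np.cumsum(_conditional(matrices[pid]), axis=1) for pid in pops_present}

    seg_len = np.asarray(seg_len, dtype=float)
    weights = seg_len * np.array([pop_total[p] for p in seg_pop])
    mean_total = float(weights.sum())
    n_mut = rng.poisson(mean_total) if mean_total > 0 else 0
    if n_mut == 0:
        return VariantTable.from_carriers([], [], [], [], hap_offsets)

    seg_idx = rng.choice(weights.size, size=n_mut, p=weights / mean_total)
    sites = np.empty(n_mut, dtype=np.int64)
    derived = np.empty(n_mut, dtype=np.uint8)
    mut_pop = np.array(seg_pop, dtype=object)[seg_idx]
    for pid in pops_present:
        sel = np.flatnonzero(mut_pop == pid)
        if not sel.size:
            continue
        cum = site_cum[pid]
        s = np.searchsorted(cum, rng.random(sel.size) * cum[-1], side="right")
        s = np.minimum(s, cum.size - 1)
        sites[sel] = s
        rows = cond_cum[pid][tri[s]]
        slot = (rows < rng.random((sel.size, 1)) * rows[:, -1:]).sum(axis=1)
        slot = np.minimum(slot, 2)
        derived[sel] = _DERIVED_CODE[tri[s], slot]

    # biallelic filter: drop sites receiving more than one mutation
    uniq, first, counts = np.unique(sites, return_index=True, return_counts=True)
    keep = first[counts == 1]
    keep.sort()

    children = genealogy.children()
    positions, tris, ders, carriers = [], [], [], []
    for i in keep.tolist():
        node = seg_node[int(seg_idx[i])]
        leaves = genealogy.descendant_leaves(node, children)
        positions.append(site_lo + int(sites[i]))
        tris.append(int(tri[sites[i]]))
        ders.append(int(derived[i]))
        carriers.append(leaves)
    return VariantTable.from_carriers(positions, tris, ders, carriers, hap_offsets)


def _conditional(matrix: MutationRateMatrix) -> np.ndarray:
    totals = matrix.triplet_totals[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        cond = np.where(totals > 0, matrix.rates / np.where(totals > 0, totals, 1.0), 1.0 / 3.0)
    return cond


def _hap_offsets(genealogy: Genealogy) -> dict:
    offsets, off = {}, 0
    for pid, idx in genealogy.sample_index.items():
        offsets[pid] = (off, off + idx.size)
        off += idx.size
    return offsets


# ---------------------------------------------------------------------------
# whole-dataset driver


def simulate_dataset(
    model: PopulationModel,
    seq: AncestralSequence,
    matrix: Union[MutationRateMatrix, Mapping[str, MutationRateMatrix]],
    samples: Mapping[str, int],
    window_length: int = DEFAULT_WINDOW_LENGTH,
    seed=None,
) -> VariantTable:
    """Simulate variation over a whole sequence: the sequence is cut into
    ``window_length`` pieces, each gets an independent genealogy (the
    recombination approximation), and the per-window variant tables are
    concatenated with global coordinates."""
    if window_length < 3:
        raise ValueError("window_length must be at least 3")
    if window_length > len(seq):
        raise ValueError("window_length exceeds sequence length")
    seed_seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    starts = list(range(0, len(seq), int(window_length)))
    tables = []
    children = seed_seq.spawn(2 * len(starts))
    for w, start in enumerate(starts):
        end = min(start + int(window_length), len(seq))
        if end - start < 3:
            continue
        gen = simulate_genealogy(model, samples, seed=children[2 * w])
        tables.append(place_mutations(gen, seq, matrix, seed=children[2 * w + 1], window=(start, end)))
    return VariantTable.concat(tables)


# ---------------------------------------------------------------------------
# forward Wright-Fisher oracle


def forward_wf_oracle(
    model: PopulationModel,
    samples: Mapping[str, int],
    seq: AncestralSequence,
    matrix: Union[MutationRateMatrix, Mapping[str, MutationRateMatrix]],
    seed=None,
    window: Optional[tuple] = None,
) -> VariantTable:
    """Brute-force forward Wright-Fisher simulation for tiny populations.

    Discrete generations, haploid gamete resampling (the neutral diploid WF
    model), per-site mutation at the ancestral-context rates, a 10*Ne
    burn-in before the oldest event, and sampling at the present; output
    matches :func:`place_mutations` (biallelic rows only, mutation contexts
    read from the ancestral sequence).  Supports constant epoch sizes and
    splits; growth or migration are outside the oracle's scope.  All sizes
    must be at most ``WF_MAX_N``.
    """
    problems = validate(model)
    if problems:
        raise ValueError("invalid model: " + "; ".join(problems))
    if model.migrations:
        raise NotImplementedError("the WF oracle does not support migration")
    for p in model.populations:
        for e in p.epochs:
            if e.growth_rate != 0.0:
                raise NotImplementedError("the WF oracle does not support growth epochs")
            if e.population_size > WF_MAX_N:
                raise ValueError(f"population {p.id}: N={e.population_size} exceeds the oracle guard {WF_MAX_N}")
            if e.population_size != int(e.population_size):
                raise ValueError("the WF oracle needs integer population sizes")

    rng = np.random.default_rng(seed)
    lo, hi = window if window is not None else (0, len(seq))
    site_lo, site_hi = max(lo, 1), min(hi, len(seq) - 1)
    tri = seq.triplet_codes()[site_lo - 1 : site_hi - 1]
    L = tri.size
    pop_order = [p.id for p in model.populations]
    matrices = _resolve_matrices(matrix, pop_order)
    site_rate = {pid: matrices[pid].triplet_totals[tri] for pid in pop_order}
    site_cum = {pid: np.cumsum(r) for pid, r in site_rate.items()}
    cond_cum = {pid: np.cumsum(_conditional(matrices[pid]), axis=1) for pid in pop_order}

    root = model.root
    events = sorted(model.splits, key=lambda s: -s.time)  # forward order
    oldest = events[0].time if events else 0.0
    burnin = 10.0 * model.population(root).size_at(oldest)
    horizon = int(math.ceil(burnin + oldest))

    # haplotype state: most-recent mutation-event id per site (0 = ancestral)
    def pop_size(pid: str, t_back: float) -> int:
        return int(model.population(pid).size_at(max(t_back, 0.0)))

    state: dict = {root: np.zeros((2 * pop_size(root, oldest), L), dtype=np.uint16)}
    event_site: list = [0]  # event id -> site (index 0 unused)
    event_base: list = [0]

    def step(G: np.ndarray, pid: str, new_n_hap: int) -> np.ndarray:
        parents = rng.integers(0, G.shape[0], size=new_n_hap)
        G = G[parents]
        lam = float(site_rate[pid].sum()) * new_n_hap
        n_mut = rng.poisson(lam) if lam > 0 else 0
        if n_mut:
            cum = site_cum[pid]
            ss = np.searchsorted(cum, rng.random(n_mut) * cum[-1], side="right")
            ss = np.minimum(ss, cum.size - 1)
            haps = rng.integers(0, new_n_hap, size=n_mut)
            for s_i, h in zip(ss.tolist(), haps.tolist()):
                rows = cond_cum[pid][tri[s_i]]
                slot = int(np.searchsorted(rows, rng.random() * rows[-1], side="right"))
                slot = min(slot, 2)
                eid = len(event_site)
                if eid > np.iinfo(np.uint16).max:
                    raise RuntimeError("too many mutation events for the oracle's id space")
                event_site.append(s_i)
                event_base.append(int(_DERIVED_CODE[tri[s_i], slot]))
                G[h, s_i] = eid
        return G

    split_index = {int(round(s.time)): s for s in events}
    for g in range(horizon):
        t_back = horizon - g - 1  # backward time after this generation
        for pid in list(state):
            state[pid] = step(state[pid], pid, 2 * pop_size(pid, t_back))
        s = split_index.get(t_back + 1)
        if s is not None and s.child_population not in state:
            parent_G = state[s.parent_population]
            n_child = 2 * pop_size(s.child_population, t_back)
            founders = rng.integers(0, parent_G.shape[0], size=n_child)
            state[s.child_population] = parent_G[founders].copy()

    # sample the present-day populations
    hap_offsets, off = {}, 0
    sampled = []
    pop_of_hap = []
    for pid in pop_order:
        n = int(samples.get(pid, 0))
        if n == 0:
            continue
        G = state[pid]
        rows = rng.choice(G.shape[0], size=n, replace=False)
        sampled.append(G[rows])
        hap_offsets[pid] = (off, off + n)
        off += n
        pop_of_hap.extend([pid] * n)
    S = np.vstack(sampled) if sampled else np.zeros((0, L), dtype=np.uint16)

    positions, tris, ders, carriers = [], [], [], []
    poly_sites = np.flatnonzero((S != 0).any(axis=0))
    for s_i in poly_sites.tolist():
        col = S[:, s_i]
        ids = np.unique(col[col != 0])
        if ids.size != 1:
            continue  # multiple mutation events visible: not biallelic
        hit = np.flatnonzero(col == ids[0])
        if hit.size == col.size:
            continue  # derived allele fixed in the sample: not segregating
        positions.append(site_lo + s_i)
        tris.append(int(tri[s_i]))
        ders.append(event_base[int(ids[0])])
        carriers.append(hit.astype(np.int32))
    return VariantTable.from_carriers(positions, tris, ders, carriers, hap_offsets)
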