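"""Heterochronous structured coalescent for a single mtDNA locus.

One simulated dataset is one genealogy: serially-sampled (dated) haploid
tips in up to three regional demes, pairwise coalescence within a deme at
rate k(k-1)/(2 N_e) per generation, pulse admixture events (each destination
lineage relocates to the source deme with probability m at exactly time t,
backward in time), and regional splits merging demes into a single ancestral
population in which the final coalescences are guaranteed.

Mutations are laid on the genealogy as a Poisson process of rate
``mu_per_site * L`` per generation of branch length, each hit at a uniform
site; the substituted base is drawn from the jump chain of an HKY model
(transition bias ``kappa``, stationary ``base_frequencies``).  Multiple hits
at a site are allowed, so the output is finite-sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .config import CENTRAL_EUROPE, EASTERN_EUROPE, NEAR_EAST
from .demography import DemographicModel, ParameterDraw

BASES = np.array(["A", "C", "G", "T"])
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
# transitions under the A=0,C=1,G=2,T=3 encoding: A<->G, C<->T
_TRANSITION_PARTNER = np.array([2, 3, 0, 1])


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class PulseRecord:
    """Outcome of one admixture pulse: which lineages relocated."""

    event_id: int
    time_gen: float
    candidates: tuple[int, ...]  # node ids present in the destination deme
    moved: tuple[int, ...]


@dataclass
class Genealogy:
    """A binary genealogy with dated tips.

    Nodes ``0..n_tips-1`` are tips; internal nodes follow in coalescence
    order, the last one being the root.  ``parents[root] == -1``.
    """

    times: np.ndarray  # age of each node, generations before present
    parents: np.ndarray  # parent node id, -1 for the root
    tip_ids: tuple[str, ...]
    tip_populations: tuple[str, ...]
    pulse_log: tuple[PulseRecord, ...] = ()

    @property
    def n_tips(self) -> int:
        return len(self.tip_ids)

    @property
    def n_nodes(self) -> int:
        return len(self.times)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parents == -1)[0])

    @property
    def tmrca(self) -> float:
        return float(self.times[self.root])

    def branch_lengths(self) -> np.ndarray:
        """Length (generations) of the branch above each non-root node."""
        bl = np.zeros(self.n_nodes)
        has_parent = self.parents >= 0
        bl[has_parent] = self.times[self.parents[has_parent]] - self.times[has_parent]
        return bl

    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for node, parent in enumerate(self.parents):
            if parent >= 0:
                ch[parent].append(node)
        return ch

    def newick(self) -> str:
        """Newick string with branch lengths in generations."""
        ch = self.children()

        def rec(node: int) -> str:
            if node < self.n_tips:
                label = self.tip_ids[node]
            else:
                label = ""
            if ch[node]:
                inner = ",".join(rec(c) for c in ch[node])
                label = f"({inner}){label}"
            parent = self.parents[node]
            if parent < 0:
                return label
            return f"{label}:{self.times[parent] - self.times[node]:.8g}"

        return rec(self.root) + ";"


def _deme_index(region: str) -> int:
    return {CENTRAL_EUROPE: 0, EASTERN_EUROPE: 1, NEAR_EAST: 2}[region]


def simulate_genealogy(
    model: DemographicModel,
    draw: ParameterDraw,
    seed: int | np.random.Generator,
) -> Genealogy:
    """Simulate one genealogy under ``model`` with parameters ``draw``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    v = draw.values
    if draw.model_name != model.name:
        raise SimulationError(
            f"draw is for model {draw.model_name!r}, not {model.name!r}"
        )

    gen_time = model.generation_time_years
    tips: list[tuple[float, int, str, str]] = []  # (age_gen, deme, id, pop)
    for pop in model.populations:
        for j, age in enumerate(pop.ages_gen(gen_time)):
            tips.append((age, _deme_index(pop.region), f"{pop.name}_{j}", pop.name))
    tips.sort(key=lambda t: (t[0], t[2]))
    n_tips = len(tips)

    times = [t[0] for t in tips]
    parents = [-1] * n_tips
    tip_ids = tuple(t[2] for t in tips)
    tip_pops = tuple(t[3] for t in tips)

    t_cn = v["t_split_CE_NE"]
    t_ee = v["t_split_EE"]
    # deme sizes by phase; after t_split_EE only the ancestral deme remains
    sizes = np.array(
        [v["N_CentralEurope"], v["N_EasternEurope"], v["N_NearEast"]], dtype=float
    )

    # scheduled (time, priority, kind, payload); priority orders ties:
    # tip entries first, then pulses, then splits
    schedule: list[tuple[float, int, int, object]] = []
    for i, (age, deme, _id, _pop) in enumerate(tips):
        schedule.append((age, 0, 0, (i, deme)))
    for e in model.events:
        schedule.append(
            (v[e.time_param], 1, 1, (e.event_id, _deme_index(e.source_region),
                                     _deme_index(e.dest_region), v[e.proportion_param]))
        )
    schedule.append((t_cn, 2, 2, (_deme_index(CENTRAL_EUROPE), _deme_index(NEAR_EAST))))
    schedule.append((t_ee, 2, 2, (_deme_index(EASTERN_EUROPE), _deme_index(NEAR_EAST))))
    schedule.sort(key=lambda s: (s[0], s[1]))

    active: list[list[int]] = [[], [], []]
    pulse_log: list[PulseRecord] = []
    t = 0.0
    next_node = n_tips

    def coalesce_until(t_stop: float) -> None:
        nonlocal t, next_node
        while True:
            waits = []
            for d in range(3):
                k = len(active[d])
                if k >= 2:
                    rate = k * (k - 1) / (2.0 * sizes[d])
                    waits.append((t + rng.exponential(1.0 / rate), d))
            if not waits:
                t = t_stop
                return
            t_next, d = min(waits)
            if t_next >= t_stop:
                t = t_stop
                return
            t = t_next
            i, j = rng.choice(len(active[d]), size=2, replace=False)
            a, b = active[d][i], active[d][j]
            times.append(t)
            parents.append(-1)
            parents[a] = next_node
            parents[b] = next_node
            # remove higher index first
            for idx in sorted((i, j), reverse=True):
                active[d].pop(idx)
            active[d].append(next_node)
            next_node += 1

    for ev_time, _prio, kind, payload in schedule:
        coalesce_until(ev_time)
        if kind == 0:
            node, deme = payload  # tip entry
            # size after EE split: everything lives in the ancestral deme
            if ev_time >= t_ee:
                deme = _deme_index(NEAR_EAST)
            elif deme == _deme_index(CENTRAL_EUROPE) and ev_time >= t_cn:
                deme = _deme_index(NEAR_EAST)
            active[deme].append(node)
        elif kind == 1:
            event_id, src, dst, m = payload
            candidates = tuple(active[dst])
            moved = []
            for node in candidates:
                if rng.random() < m:
                    moved.append(node)
            for node in moved:
                active[dst].remove(node)
                active[src].append(node)
            pulse_log.append(
                PulseRecord(event_id, ev_time, candidates, tuple(moved))
            )
        else:
            child, parent = payload  # deme merge, backward in time
            active[parent].extend(active[child])
            active[child] = []
            if payload == (_deme_index(EASTERN_EUROPE), _deme_index(NEAR_EAST)):
                sizes[_deme_index(NEAR_EAST)] = v["N_ancestral"]

    # final coalescence in the ancestral deme
    coalesce_until(np.inf)

    return Genealogy(
        times=np.asarray(times, dtype=float),
        parents=np.asarray(parents, dtype=np.int64),
        tip_ids=tip_ids,
        tip_populations=tip_pops,
        pulse_log=tuple(pulse_log),
    )


@dataclass(frozen=True)
class MutationParams:
    """Finite-sites mutation settings for one locus."""

    locus_length: int = 16569
    mu_per_site: float = 2e-8
    model: str = "HKY"
    ts_tv_ratio: float = 20.0  # kappa; 1.0 gives Jukes-Cantor-like behaviour
    base_frequencies: tuple[float, float, float, float] = (0.309, 0.313, 0.131, 0.247)

    def __post_init__(self) -> None:
        if self.locus_length < 1:
            raise SimulationError("locus_length must be >= 1")
        if self.mu_per_site < 0:
            raise SimulationError("mu_per_site must be >= 0")
        freqs = np.asarray(self.base_frequencies, dtype=float)
        if abs(freqs.sum() - 1.0) > 1e-12:
            raise SimulationError("base_frequencies must sum to 1")

    def jump_matrix(self) -> np.ndarray:
        """P[i, j]: probability the new base is j given a hit at base i."""
        freqs = np.asarray(self.base_frequencies, dtype=float)
        P = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                rate = freqs[j]
                if _TRANSITION_PARTNER[i] == j:
                    rate *= self.ts_tv_ratio
                P[i, j] = rate
            P[i] /= P[i].sum()
        return P


@dataclass
class Alignment:
    """An mtDNA alignment stored as variant columns over a background.

    ``variant_matrix[i, k]`` is the base (0..3) of sample ``i`` at variant
    position ``variant_positions[k]``; every other position carries the
    shared ``background`` base.  ``sequences`` materialises full strings.
    """

    ids: tuple[str, ...]
    populations: Mapping[str, str]  # sample id -> population label
    length: int
    variant_positions: np.ndarray  # sorted, int
    variant_matrix: np.ndarray  # n_samples x n_variant, uint8
    background: np.ndarray  # length L, uint8

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise SimulationError("duplicate sample ids")
        missing = [i for i in self.ids if i not in self.populations]
        if missing:
            raise SimulationError(f"samples without metadata: {missing}")

    @property
    def n_samples(self) -> int:
        return len(self.ids)

    def population_of(self, sample_id: str) -> str:
        return self.populations[sample_id]

    def sample_indices(self, population: str) -> np.ndarray:
        return np.array(
            [k for k, i in enumerate(self.ids) if self.populations[i] == population],
            dtype=int,
        )

    @property
    def population_names(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for i in self.ids:
            seen.setdefault(self.populations[i], None)
        return tuple(seen)

    def sequence(self, k: int) -> str:
        row = self.background.copy()
        row[self.variant_positions] = self.variant_matrix[k]
        return "".join(BASES[row])

    @property
    def sequences(self) -> dict[str, str]:
        return {sid: self.sequence(k) for k, sid in enumerate(self.ids)}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return (
            self.ids == other.ids
            and dict(self.populations) == dict(other.populations)
            and self.sequences == other.sequences
        )

    @classmethod
    def from_sequences(
        cls, sequences: Mapping[str, str], populations: Mapping[str, str]
    ) -> "Alignment":
        ids = tuple(sequences)
        lengths = {len(s) for s in sequences.values()}
        if len(lengths) > 1:
            raise SimulationError("ragged alignment: sequences differ in length")
        L = lengths.pop() if lengths else 0
        mat = np.zeros((len(ids), L), dtype=np.uint8)
        for k, sid in enumerate(ids):
            seq = sequences[sid].upper()
            bad = set(seq) - set("ACGT")
            if bad:
                raise SimulationError(f"sample {sid!r}: non-ACGT characters {bad}")
            mat[k] = np.frombuffer(seq.encode(), dtype=np.uint8)
        # recode ASCII -> 0..3
        code = np.zeros(256, dtype=np.uint8)
        for b, i in BASE_INDEX.items():
            code[ord(b)] = i
        mat = code[mat]
        variable = np.flatnonzero((mat != mat[0]).any(axis=0)) if len(ids) else np.array([], int)
        background = mat[0].copy() if len(ids) else np.zeros(L, dtype=np.uint8)
        return cls(
            ids=ids,
            populations=dict(populations),
            length=L,
            variant_positions=variable,
            variant_matrix=mat[:, variable].copy(),
            background=background,
        )


def mutate(
    tree: Genealogy,
    params: MutationParams,
    seed: int | np.random.Generator,
) -> Alignment:
    """Superimpose mutations on a genealogy and return the tip alignment."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = params.locus_length
    freqs = np.asarray(params.base_frequencies, dtype=float)
    cum = np.cumsum(freqs)

    # root sequence from the stationary distribution
    background = np.searchsorted(cum, rng.random(L)).astype(np.uint8)

    bl = tree.branch_lengths()
    n_mut = rng.poisson(params.mu_per_site * L * bl)
    total = int(n_mut.sum())
    if total == 0 or tree.n_tips == 0:
        return Alignment(
            ids=tree.tip_ids,
            populations=dict(zip(tree.tip_ids, tree.tip_populations)),
            length=L,
            variant_positions=np.array([], dtype=int),
            variant_matrix=np.zeros((tree.n_tips, 0), dtype=np.uint8),
            background=background,
        )

    sites = rng.integers(0, L, size=total)
    uniq_sites, site_local = np.unique(sites, return_inverse=True)
    P = params.jump_matrix()
    cumP = np.cumsum(P, axis=1)

    # assign mutations to branches (node owning the branch above it)
    branch_of = np.repeat(np.arange(tree.n_nodes), n_mut)
    mut_by_node: list[list[int]] = [[] for _ in range(tree.n_nodes)]
    for m_idx in range(total):
        mut_by_node[branch_of[m_idx]].append(m_idx)

    ch = tree.children()
    root = tree.root
    n_var = len(uniq_sites)
    states = np.empty((tree.n_nodes, n_var), dtype=np.uint8)
    root_state = background[uniq_sites].copy()

    # preorder traversal applying each branch's mutations in random order
    u = rng.random(total)
    stack = [root]
    states[root] = root_state
    order = np.arange(total)
    while stack:
        node = stack.pop()
        if node != root:
            state = states[tree.parents[node]].copy()
            muts = mut_by_node[node]
            if muts:
                rng.shuffle(muts)
                for m_idx in muts:
                    k = site_local[m_idx]
                    cur = state[k]
                    state[k] = np.searchsorted(cumP[cur], u[m_idx])
                states[node] = state
            else:
                states[node] = state
        stack.extend(ch[node])

    tip_states = states[: tree.n_tips]
    # keep only sites where tips actually differ from the background or
    # from one another (back-mutations can restore the root base)
    keep = np.flatnonzero(
        (tip_states != background[uniq_sites][None, :]).any(axis=0)
    )
    return Alignment(
        ids=tree.tip_ids,
        populations=dict(zip(tree.tip_ids, tree.tip_populations)),
        length=L,
        variant_positions=uniq_sites[keep],
        variant_matrix=tip_states[:, keep].copy(),
        background=background,
    )


def write_fasta(aln: Alignment, path) -> None:
    """Write an alignment to FASTA; headers carry the sample id verbatim."""
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in aln.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path, metadata: Mapping[str, str]) -> Alignment:
    """Read a FASTA alignment; ``metadata`` maps sample id -> population."""
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise SimulationError(f"duplicate sample id {rec.id!r} in {path}")
        sequences[rec.id] = str(rec.seq)
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) > 1:
        raise SimulationError(f"ragged FASTA {path}: lengths {sorted(lengths)}")
    return Alignment.from_sequences(sequences, metadata)
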