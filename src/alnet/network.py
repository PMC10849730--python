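"""Construction of the antennal-lobe network.

The small network contains 100 PNs and 280 LNs organised into 20 glomeruli of
5 PNs and 12 unipolar LNs each, plus 40 multipolar LNs providing global
inhibition.  Directed connections are independent Bernoulli draws with the
class-specific probabilities:

    PN -> PN                          0
    PN -> unipolar LN                 0.4
    PN -> multipolar LN               0.4
    unipolar LN -> PN (same glom.)    0
    unipolar LN -> PN (diff. glom.)   0.5
    unipolar LN -> unipolar LN same   0
    unipolar LN -> unipolar LN diff.  0.4
    unipolar LN -> multipolar LN      0.3
    multipolar LN -> PN               0.3
    multipolar LN -> multipolar LN    0.1
    multipolar LN -> unipolar LN      0.4

Every LN -> PN connection carries both a fast GABA_A and a slow inhibitory
component.  A large variant (400 PNs / 1120 LNs, uniform p = 0.125 for
LN->LN, LN->PN and PN->LN, no PN->PN) accommodates gas-sensor inputs, and a
reduced variant (same composition rules, fewer glomeruli) supports
desk-scale experiments.

The printed maximal conductances (uS) are totals per postsynaptic cell and
synapse class, shared equally among that cell's inputs of the class, so the
overall synaptic drive is independent of the realised in-degree and of
network scale.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import neurons
from .synapses import LARGE_NET_CONDUCTANCES, SMALL_NET_CONDUCTANCES

# synapse kind codes used by the flat connection arrays
KIND_GABA_A = 0
KIND_NACH = 1
KIND_SLOW = 2
KIND_NAMES = {KIND_GABA_A: "GABA_A", KIND_NACH: "nACh", KIND_SLOW: "slow"}

US_TO_MS = 1e-3  # uS -> mS

# channel column order in the per-neuron conductance matrix
CHANNEL_ORDER = ("Na", "K", "A", "T", "h")


@dataclass
class Glomerulus:
    id: int
    pn_ids: np.ndarray
    uni_ln_ids: np.ndarray


@dataclass
class Network:
    """Flat-array representation of one antennal-lobe network.

    Neurons are indexed PNs first, then unipolar LNs, then multipolar LNs.
    Connection arrays are parallel; LN->PN fast and slow entries are stored
    in identical (pre, post) order so the k-th fast entry and the k-th slow
    entry belong to the same anatomical connection and share facilitation
    events by construction.
    """

    variant: str
    seed: int
    n_pn: int
    n_uni: int
    n_multi: int
    glomeruli: list = field(default_factory=list)

    # neuron parameter arrays (totals: conductance density * area, in mS)
    is_pn: np.ndarray = None
    cm: np.ndarray = None
    gl: np.ndarray = None
    gkl: np.ndarray = None
    gch: np.ndarray = None          # (n, 5) in CHANNEL_ORDER
    area: np.ndarray = None

    # connection arrays
    pre: np.ndarray = None
    post: np.ndarray = None
    kind: np.ndarray = None
    g: np.ndarray = None            # per-connection max conductance, mS
    F: np.ndarray = None
    plastic: np.ndarray = None
    env_reinforced: np.ndarray = None

    # index ranges into the connection arrays, by class
    sl_ln_pn_fast: slice = None
    sl_ln_pn_slow: slice = None
    sl_ln_ln: slice = None
    sl_pn_ln: slice = None

    frozen: bool = False

    # mutable dynamical state.  Synaptic receptor/effector states evolve
    # identically for every connection sharing a presynaptic neuron (the
    # ODEs depend only on the presynaptic voltage or spike time), so they
    # are stored once per presynaptic neuron; the per-connection quantity
    # is the facilitation F.
    V: np.ndarray = None
    gate: np.ndarray = None         # (n, 8)
    ca: np.ndarray = None
    O_gaba: np.ndarray = None       # fast GABA_A open fraction per pre neuron
    O_ach: np.ndarray = None        # nACh open fraction per pre neuron
    R_slow: np.ndarray = None       # slow-synapse receptor per pre neuron
    G_slow: np.ndarray = None       # slow-synapse G-protein per pre neuron
    last_spike: np.ndarray = None
    above: np.ndarray = None

    # ------------------------------------------------------------------
    @property
    def n_ln(self) -> int:
        return self.n_uni + self.n_multi

    @property
    def n_neurons(self) -> int:
        return self.n_pn + self.n_ln

    @property
    def n_connections(self) -> int:
        return len(self.pre)

    def role_of(self, i: int) -> str:
        return "PN" if i < self.n_pn else "LN"

    def subtype_of(self, i: int) -> str:
        if i < self.n_pn:
            return "PN"
        return "uniLN" if i < self.n_pn + self.n_uni else "multiLN"

    def glomerulus_of(self, i: int) -> int:
        """Glomerulus id of neuron i, or -1 for multipolar LNs / large nets."""
        for gl in self.glomeruli:
            if i in gl.pn_ids or i in gl.uni_ln_ids:
                return gl.id
        return -1

    # ------------------------------------------------------------------
    def reset_state(self):
        """Re-settled initial conditions: V = EL, gates at x_inf(EL), Ca at
        equilibrium, all synapses closed."""
        n = self.n_neurons
        self.V = np.empty(n)
        self.gate = np.zeros((n, 8))
        self.ca = np.full(n, 2.4e-4)
        for role, sel in (("PN", slice(0, self.n_pn)),
                          ("LN", slice(self.n_pn, n))):
            st = neurons.initial_state(role)
            self.V[sel] = st.V
            vals = _gate_vector(st)
            self.gate[sel] = vals
        self.O_gaba = np.zeros(n)
        self.O_ach = np.zeros(n)
        self.R_slow = np.zeros(n)
        self.G_slow = np.zeros(n)
        self.last_spike = np.full(n, -1e9)
        self.above = np.zeros(n, dtype=np.bool_)

    def freeze(self):
        self.frozen = True

    def clone(self) -> "Network":
        return copy.deepcopy(self)

    def reset_environment_flags(self):
        """Mark every plastic connection as not-yet-reinforced; called at the
        start of training on a new environment."""
        self.env_reinforced[:] = False

    # ------------------------------------------------------------------
    def adjacency_csr(self):
        """(by_pre_ptr, by_pre_idx, by_post_ptr, by_post_idx): connection
        indices grouped by presynaptic and by postsynaptic neuron."""
        n, m = self.n_neurons, self.n_connections
        order_pre = np.argsort(self.pre, kind="stable").astype(np.int64)
        ptr_pre = np.zeros(n + 1, dtype=np.int64)
        np.add.at(ptr_pre, self.pre + 1, 1)
        ptr_pre = np.cumsum(ptr_pre)
        order_post = np.argsort(self.post, kind="stable").astype(np.int64)
        ptr_post = np.zeros(n + 1, dtype=np.int64)
        np.add.at(ptr_post, self.post + 1, 1)
        ptr_post = np.cumsum(ptr_post)
        return ptr_pre, order_pre, ptr_post, order_post

    def pn_percept_blocks(self, n_percepts: int):
        """Contiguous PN index blocks, one per percept."""
        return _split_blocks(self.n_pn, n_percepts)

    def uni_ln_percept_blocks(self, n_percepts: int):
        """Contiguous unipolar-LN blocks mirroring the PN partition,
        offset to absolute neuron indices."""
        blocks = _split_blocks(self.n_uni, n_percepts)
        return [(self.n_pn + a, self.n_pn + b) for a, b in blocks]

    # ------------------------------------------------------------------
    def nodes_table(self) -> pd.DataFrame:
        glom = np.full(self.n_neurons, -1)
        for gl in self.glomeruli:
            glom[gl.pn_ids] = gl.id
            glom[gl.uni_ln_ids] = gl.id
        return pd.DataFrame({
            "id": np.arange(self.n_neurons),
            "role": [self.role_of(i) for i in range(self.n_neurons)],
            "subtype": [self.subtype_of(i) for i in range(self.n_neurons)],
            "glomerulus": glom,
        })

    def synapse_state_table(self) -> pd.DataFrame:
        """Per-connection snapshot (pre_id, post_id, kind, gmax_uS, F,
        O_or_G) of the current dynamical state."""
        state = np.empty(self.n_connections)
        for sl, arr in ((self.sl_ln_pn_fast, self.O_gaba),
                        (self.sl_ln_ln, self.O_gaba),
                        (self.sl_pn_ln, self.O_ach),
                        (self.sl_ln_pn_slow, self.G_slow)):
            state[sl] = arr[self.pre[sl]]
        df = self.edges_table()
        df["O_or_G"] = state
        return df

    def edges_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pre_id": self.pre,
            "post_id": self.post,
            "pre_type": [self.subtype_of(i) for i in self.pre],
            "post_type": [self.subtype_of(i) for i in self.post],
            "kind": [KIND_NAMES[k] for k in self.kind],
            "gmax_uS": self.g / US_TO_MS,
            "F": self.F,
            "plastic": self.plastic,
        })


def _gate_vector(state: neurons.NeuronState):
    """Pack a NeuronState's gating dict into the engine's 8-column layout:
    Na_m, Na_h, K_m, A_m, A_h, T_m, T_h, h_m."""
    g = state.gating
    out = np.zeros(8)
    out[0], out[1] = g["Na"].m, g["Na"].h
    out[2] = g["K"].m
    if "A" in g:
        out[3], out[4] = g["A"].m, g["A"].h
    out[5], out[6] = g["T"].m, g["T"].h
    if "h" in g:
        out[7] = g["h"].m
    return out


def _split_blocks(n: int, k: int):
    """k near-equal contiguous [start, stop) blocks covering range(n)."""
    edges = np.linspace(0, n, k + 1).round().astype(int)
    return [(int(edges[i]), int(edges[i + 1])) for i in range(k)]


def _neuron_arrays(n_pn: int, n_ln: int):
    n = n_pn + n_ln
    is_pn = np.zeros(n, dtype=np.bool_)
    is_pn[:n_pn] = True
    cm = np.empty(n)
    gl = np.empty(n)
    gkl = np.empty(n)
    area = np.empty(n)
    gch = np.zeros((n, 5))
    for role, sel in (("PN", slice(0, n_pn)), ("LN", slice(n_pn, n))):
        p = neurons.passive_for_role(role)
        cm[sel] = p.Cm
        gl[sel] = p.gL * p.area
        gkl[sel] = p.gKL * p.area
        area[sel] = p.area
        for c in neurons.channels_for_role(role):
            gch[sel, CHANNEL_ORDER.index(c.name)] = c.gmax * p.area
    return is_pn, cm, gl, gkl, gch, area


def _finalize(net: Network, ln_pn_pairs, ln_ln_pairs, pn_ln_pairs, conduct,
              facilitate_slow: bool = False):
    """Assemble the parallel connection arrays with in-degree-shared
    conductances and initialise state."""
    ln_pn = np.asarray(ln_pn_pairs, dtype=np.int64).reshape(-1, 2)
    ln_ln = np.asarray(ln_ln_pairs, dtype=np.int64).reshape(-1, 2)
    pn_ln = np.asarray(pn_ln_pairs, dtype=np.int64).reshape(-1, 2)

    def shared(total_uS, posts):
        counts = np.bincount(posts, minlength=net.n_neurons)
        return total_uS * US_TO_MS / counts[posts]

    g_fast_pn = shared(conduct["gaba_ln_pn"], ln_pn[:, 1]) if len(ln_pn) else np.empty(0)
    g_slow_pn = shared(conduct["slow_ln_pn"], ln_pn[:, 1]) if len(ln_pn) else np.empty(0)
    g_ln_ln = shared(conduct["gaba_ln_ln"], ln_ln[:, 1]) if len(ln_ln) else np.empty(0)
    g_pn_ln = shared(conduct["ach_pn_ln"], pn_ln[:, 1]) if len(pn_ln) else np.empty(0)

    # group order: fast LN->PN, LN->LN, PN->LN, slow LN->PN.  The k-th fast
    # LN->PN entry and the k-th slow entry are the same anatomical
    # connection; grouping keeps each state family (O vs R/G) contiguous.
    pres = np.concatenate([ln_pn[:, 0], ln_ln[:, 0], pn_ln[:, 0], ln_pn[:, 0]])
    posts = np.concatenate([ln_pn[:, 1], ln_ln[:, 1], pn_ln[:, 1], ln_pn[:, 1]])
    kinds = np.concatenate([
        np.full(len(ln_pn), KIND_GABA_A, dtype=np.int8),
        np.full(len(ln_ln), KIND_GABA_A, dtype=np.int8),
        np.full(len(pn_ln), KIND_NACH, dtype=np.int8),
        np.full(len(ln_pn), KIND_SLOW, dtype=np.int8),
    ])
    gs = np.concatenate([g_fast_pn, g_ln_ln, g_pn_ln, g_slow_pn])

    net.pre = pres.astype(np.int64)
    net.post = posts.astype(np.int64)
    net.kind = kinds
    net.g = gs
    m = len(pres)
    net.F = np.ones(m)
    net.plastic = np.zeros(m, dtype=np.bool_)
    a, b, c = len(ln_pn), len(ln_ln), len(pn_ln)
    net.sl_ln_pn_fast = slice(0, a)
    net.sl_ln_ln = slice(a, a + b)
    net.sl_pn_ln = slice(a + b, a + b + c)
    net.sl_ln_pn_slow = slice(a + b + c, m)
    # Facilitation acts on the fast GABA_A conductances (LN->PN, LN->LN).
    # Whether the slow G-protein component shares the facilitation variable
    # is a model choice; with its ~1 s receptor memory a facilitated slow
    # synapse clamps the whole PN population after training, abolishing the
    # odor-specific contrast the learning is supposed to create, so the
    # default facilitates the fast component only.
    net.plastic[net.sl_ln_pn_fast] = True
    net.plastic[net.sl_ln_ln] = True
    net.plastic[net.sl_ln_pn_slow] = facilitate_slow
    net.env_reinforced = np.zeros(m, dtype=np.bool_)
    net.reset_state()
    return net


def _bernoulli_pairs(rng, pre_ids, post_ids, p, exclude_same=None,
                     no_self=True):
    """Ordered (pre, post) pairs drawn independently with probability p.

    ``exclude_same`` maps a neuron id to a group label; pairs within the
    same group are forbidden (same-glomerulus exclusion).
    """
    pairs = []
    for i in pre_ids:
        draws = rng.random(len(post_ids))
        for j, u in zip(post_ids, draws):
            if no_self and i == j:
                continue
            if exclude_same is not None and exclude_same.get(i) is not None \
                    and exclude_same.get(i) == exclude_same.get(j):
                continue
            if u < p:
                pairs.append((i, j))
    return pairs


def build_glomerular_network(seed: int, n_glomeruli: int = 20,
                             pn_per_glom: int = 5, uni_per_glom: int = 12,
                             n_multi: int = 40, conductances: dict | None = None,
                             variant: str = "small",
                             facilitate_slow: bool = False) -> Network:
    """Glomerular network with the Table-2 connection probabilities.

    The defaults give the standard small network (100 PN / 280 LN); passing
    fewer glomeruli builds a reduced network with identical per-glomerulus
    composition and connection rules.
    """
    conduct = dict(SMALL_NET_CONDUCTANCES)
    if conductances:
        conduct.update(conductances)
    n_pn = n_glomeruli * pn_per_glom
    n_uni = n_glomeruli * uni_per_glom
    rng = np.random.default_rng(seed)

    net = Network(variant=variant, seed=seed, n_pn=n_pn, n_uni=n_uni,
                  n_multi=n_multi)
    glom_of = {}
    for gi in range(n_glomeruli):
        pn_ids = np.arange(gi * pn_per_glom, (gi + 1) * pn_per_glom)
        uni_ids = n_pn + np.arange(gi * uni_per_glom, (gi + 1) * uni_per_glom)
        net.glomeruli.append(Glomerulus(gi, pn_ids, uni_ids))
        for i in pn_ids:
            glom_of[int(i)] = gi
        for i in uni_ids:
            glom_of[int(i)] = gi

    pns = list(range(n_pn))
    unis = list(range(n_pn, n_pn + n_uni))
    multis = list(range(n_pn + n_uni, n_pn + n_uni + n_multi))

    # inhibitory LN -> PN (unipolar cross-glomerular, multipolar global)
    ln_pn = _bernoulli_pairs(rng, unis, pns, 0.5, exclude_same=glom_of)
    ln_pn += _bernoulli_pairs(rng, multis, pns, 0.3)
    # inhibitory LN -> LN
    ln_ln = _bernoulli_pairs(rng, unis, unis, 0.4, exclude_same=glom_of)
    ln_ln += _bernoulli_pairs(rng, unis, multis, 0.3)
    ln_ln += _bernoulli_pairs(rng, multis, multis, 0.1)
    ln_ln += _bernoulli_pairs(rng, multis, unis, 0.4)
    # excitatory PN -> LN
    pn_ln = _bernoulli_pairs(rng, pns, unis, 0.4)
    pn_ln += _bernoulli_pairs(rng, pns, multis, 0.4)

    (net.is_pn, net.cm, net.gl, net.gkl, net.gch, net.area) = \
        _neuron_arrays(n_pn, n_uni + n_multi)
    return _finalize(net, ln_pn, ln_ln, pn_ln, conduct, facilitate_slow)


def build_small_network(seed: int, conductances: dict | None = None) -> Network:
    """The standard 100 PN / 280 LN network (20 glomeruli, 40 multipolar LNs)."""
    return build_glomerular_network(seed, conductances=conductances)


def build_reduced_network(seed: int, n_glomeruli: int = 8,
                          n_multi: int | None = None,
                          conductances: dict | None = None) -> Network:
    """Reduced network for desk-scale experiments; keeps the per-glomerulus
    composition (5 PNs, 12 unipolar LNs) and multipolar fraction of the small
    network.  8 glomeruli give 40 PNs / 112 LNs."""
    if n_multi is None:
        n_multi = 2 * n_glomeruli
    return build_glomerular_network(seed, n_glomeruli=n_glomeruli,
                                    n_multi=n_multi,
                                    conductances=conductances,
                                    variant="reduced")


def build_large_network(seed: int, n_pn: int = 400, n_ln: int = 1120,
                        p: float = 0.125,
                        conductances: dict | None = None) -> Network:
    """The large variant: uniform Bernoulli(p) for LN->LN, LN->PN and
    PN->LN, no PN->PN, no glomerular structure."""
    conduct = dict(LARGE_NET_CONDUCTANCES)
    if conductances:
        conduct.update(conductances)
    rng = np.random.default_rng(seed)
    net = Network(variant="large", seed=seed, n_pn=n_pn, n_uni=n_ln, n_multi=0)
    pns = list(range(n_pn))
    lns = list(range(n_pn, n_pn + n_ln))
    ln_pn = _bernoulli_pairs(rng, lns, pns, p)
    ln_ln = _bernoulli_pairs(rng, lns, lns, p)
    pn_ln = _bernoulli_pairs(rng, pns, lns, p)
    (net.is_pn, net.cm, net.gl, net.gkl, net.gch, net.area) = \
        _neuron_arrays(n_pn, n_ln)
    return _finalize(net, ln_pn, ln_ln, pn_ln, conduct)


def shuffle_inhibitory_weights(network: Network, seed: int) -> Network:
    """Control network with the trained facilitation values randomly
    permuted within each inhibitory synapse class.

    The multiset of F values over LN->PN connections (and separately over
    LN->LN connections) is preserved exactly; the fast and slow components
    of each LN->PN connection travel together; topology is unchanged.
    """
    rng = np.random.default_rng(seed)
    out = network.clone()
    fast, slow, lnln = out.sl_ln_pn_fast, out.sl_ln_pn_slow, out.sl_ln_ln
    n_pairs = fast.stop - fast.start
    perm = rng.permutation(n_pairs)
    out.F[fast] = network.F[fast][perm]
    out.F[slow] = network.F[slow][perm]
    n_lnln = lnln.stop - lnln.start
    perm2 = rng.permutation(n_lnln)
    out.F[lnln] = network.F[lnln][perm2]
    return out


def from_tables(nodes: pd.DataFrame, edges: pd.DataFrame, variant: str = "small",
                seed: int = 0) -> Network:
    """Rebuild a network from its nodes/edges tables (lossless round-trip)."""
    n_pn = int((nodes["role"] == "PN").sum())
    n_uni = int((nodes["subtype"] == "uniLN").sum())
    n_multi = int((nodes["subtype"] == "multiLN").sum())
    net = Network(variant=variant, seed=seed, n_pn=n_pn, n_uni=n_uni,
                  n_multi=n_multi)
    for gi in sorted(g for g in nodes["glomerulus"].unique() if g >= 0):
        sel = nodes[nodes["glomerulus"] == gi]
        net.glomeruli.append(Glomerulus(
            int(gi),
            sel[sel["role"] == "PN"]["id"].to_numpy(),
            sel[sel["subtype"] == "uniLN"]["id"].to_numpy()))
    (net.is_pn, net.cm, net.gl, net.gkl, net.gch, net.area) = \
        _neuron_arrays(n_pn, n_uni + n_multi)

    kind_code = {v: k for k, v in KIND_NAMES.items()}
    kinds = edges["kind"].map(kind_code).to_numpy(dtype=np.int8)
    net.pre = edges["pre_id"].to_numpy(dtype=np.int64)
    net.post = edges["post_id"].to_numpy(dtype=np.int64)
    net.kind = kinds
    net.g = edges["gmax_uS"].to_numpy(dtype=float) * US_TO_MS
    net.F = edges["F"].to_numpy(dtype=float)
    m = len(net.pre)
    if "plastic" in edges.columns:
        net.plastic = edges["plastic"].to_numpy(dtype=np.bool_)
    else:
        # default plasticity rule: inhibitory fast components only
        net.plastic = ((net.pre >= n_pn)
                       & (kinds != KIND_SLOW)).astype(np.bool_)
    net.env_reinforced = np.zeros(m, dtype=np.bool_)
    a = int((kinds == KIND_SLOW).sum())          # fast/slow LN->PN pairs
    n_gaba = int((kinds == KIND_GABA_A).sum())
    b = n_gaba - a                               # LN->LN
    c = int((kinds == KIND_NACH).sum())          # PN->LN
    net.sl_ln_pn_fast = slice(0, a)
    net.sl_ln_ln = slice(a, a + b)
    net.sl_pn_ln = slice(a + b, a + b + c)
    net.sl_ln_pn_slow = slice(a + b + c, m)
    net.reset_state()
    return net
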