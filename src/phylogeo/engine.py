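"""Constrained Bayesian MCMC, convergence diagnostics, consensus trees,
stepping-stone marginal likelihoods, and Bayes factors.

The sampler is a Metropolis(-coupled) MCMC over topology, branch lengths and
substitution-model parameters. Topological constraints are hard: any proposal
producing a tree in which a constrained taxon subset is not a clade is
rejected outright, which is equivalent to a prior placing zero mass outside
the constraint-satisfying set.

Priors (documented defaults, mirroring common Bayesian phylogenetics
practice): branch lengths iid Exponential(10); topology uniform over
constraint-satisfying trees; state frequencies Dirichlet(1,..); GTR
exchangeabilities Dirichlet(1,..) on the rate simplex; ln(kappa) ~
Normal(1, 1.25); gamma shape ~ Exponential(1); p_inv ~ Uniform(0,1).

Marginal likelihoods use stepping-stone sampling along the power-posterior
path p(theta) L(theta)^beta with Beta(0.3, 1)-quantile beta spacing,
beta_j = (j/steps)^(1/0.3). Each step's chain is initialized from the
previous step's final state, so every step doubles as the burn-in of the
next; the first (posterior) step is preceded by an explicit burn-in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import dirichlet as dirichlet_dist

from .core import ConstraintSet, CharacterMatrix, PartitionScheme, PhylogeoError, \
    Tree, TreeNode, bipartitions, normalize_split, satisfies
from .models import MkModel, SubstitutionModel, _site_logliks, compress_patterns, \
    parse_model

__all__ = [
    "McmcConfig",
    "PosteriorSample",
    "MarginalLikelihood",
    "BayesFactor",
    "run_mcmc",
    "sdsf",
    "consensus",
    "stepping_stone",
    "stepping_stone_generic",
    "bayes_factor",
    "random_constrained_tree",
]


# ---------------------------------------------------------------------------
# Configuration and sample containers
# ---------------------------------------------------------------------------

@dataclass
class McmcConfig:
    generations: int = 10_000
    sample_interval: int = 100
    burnin_fraction: float = 0.25
    n_runs: int = 2
    n_chains: int = 2              # per run: 1 cold + (n_chains - 1) heated
    heat_lambda: float = 0.1
    seed: int = 0
    brlen_prior_rate: float = 10.0
    proposal_weights: dict = field(default_factory=lambda: {
        "topology": 0.35, "brlen": 0.35, "params": 0.30})
    swap_interval: int = 10
    ss_steps: int = 50
    ss_generations_per_step: int = 200
    ss_thin: int = 1               # kernel updates between retained samples
    ss_alpha: float = 0.3
    sdsf_min_freq: float = 0.10
    sdsf_threshold: float = 0.01   # advisory stopping threshold, not enforced

    def __post_init__(self):
        if self.generations < self.sample_interval:
            raise ValueError("generations must be >= sample_interval")
        if not 0 <= self.burnin_fraction < 1:
            raise ValueError("burnin_fraction must lie in [0, 1)")


@dataclass
class RunTrace:
    generations: list = field(default_factory=list)
    trees: list = field(default_factory=list)
    lnL: list = field(default_factory=list)
    lnPrior: list = field(default_factory=list)
    params: list = field(default_factory=list)

    def post_burnin(self, frac: float):
        k = int(math.floor(len(self.trees) * frac))
        return self.trees[k:], self.lnL[k:], self.params[k:]


@dataclass
class PosteriorSample:
    runs: list
    burnin_fraction: float = 0.25
    constraint: ConstraintSet | None = None

    @property
    def trees(self):
        out = []
        for r in self.runs:
            out.extend(r.post_burnin(self.burnin_fraction)[0])
        return out

    @property
    def lnL(self):
        out = []
        for r in self.runs:
            out.extend(r.post_burnin(self.burnin_fraction)[1])
        return out

    @property
    def params(self):
        out = []
        for r in self.runs:
            out.extend(r.post_burnin(self.burnin_fraction)[2])
        return out

    def write_trace(self, path):
        with open(path, "w") as fh:
            fh.write("run\tgeneration\tlnL\tlnPrior\n")
            for i, r in enumerate(self.runs):
                for g, ll, lp in zip(r.generations, r.lnL, r.lnPrior):
                    fh.write(f"{i}\t{g}\t{ll:.6f}\t{lp:.6f}\n")

    def write_trees(self, path):
        with open(path, "w") as fh:
            for t in self.trees:
                fh.write(t.newick() + "\n")


@dataclass
class MarginalLikelihood:
    log_ml: float
    contributions: np.ndarray
    betas: np.ndarray
    se: float
    data_id: str | None = None

    def to_json_dict(self):
        return {"log_ml": self.log_ml, "se": self.se,
                "betas": list(map(float, self.betas)),
                "contributions": list(map(float, self.contributions))}


@dataclass
class BayesFactor:
    delta_ln: float
    two_delta_ln: float
    category: str
    scale: str = "2dln"

    @property
    def score(self):
        return self.two_delta_ln if self.scale == "2dln" else self.delta_ln


# ---------------------------------------------------------------------------
# Random trees under constraints
# ---------------------------------------------------------------------------

def _random_join(items, rng, lengths_rate, down_to: int):
    items = list(items)
    while len(items) > down_to:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        b = items.pop(j)
        a = items.pop(i)
        p = TreeNode()
        p.add_child(a)
        p.add_child(b)
        items.append(p)
    return items


def random_constrained_tree(taxa, constraints: ConstraintSet | None, rng,
                            brlen_rate: float = 10.0) -> Tree:
    """Random resolved unrooted tree in which every constraint is a clade."""
    taxa = list(taxa)
    subsets = sorted(constraints.subsets, key=len) if constraints else []

    def build(members, sub_constraints):
        # sub_constraints: constraints strictly inside `members`, largest first
        tops = []
        used = set()
        for s in sorted(sub_constraints, key=len, reverse=True):
            if s & used:
                continue  # nested inside an already-claimed top-level subset
            tops.append(s)
            used |= s
        items = []
        for s in tops:
            inner = [c for c in sub_constraints if c < s]
            node = build(s, inner)
            items.append(node)
        for t in sorted(set(members) - used):
            items.append(TreeNode(label=t))
        joined = _random_join(items, rng, brlen_rate, down_to=1)
        return joined[0] if len(joined) == 1 else joined

    all_set = frozenset(taxa)
    tops = []
    used = set()
    for s in sorted(subsets, key=len, reverse=True):
        if s & used:
            continue
        tops.append(s)
        used |= s
    items = [build(s, [c for c in subsets if c < s]) for s in tops]
    items += [TreeNode(label=t) for t in sorted(set(taxa) - used)]
    root = TreeNode()
    for it in _random_join(items, rng, brlen_rate, down_to=min(3, len(items))):
        root.add_child(it)
    tree = Tree(root, rooted=False)
    for n in tree.postorder():
        if n is not tree.root:
            n.length = float(rng.exponential(1.0 / brlen_rate))
    if constraints is not None and not satisfies(tree, constraints):
        raise PhylogeoError("failed to build constraint-satisfying start tree")
    return tree


def _reroot_at(tree: Tree, node: TreeNode) -> None:
    """Make `node` the root in place, preserving edge lengths (unrooted view)."""
    if node is tree.root:
        return
    path = []
    cur = node
    while cur is not None:
        path.append(cur)
        cur = cur.parent
    # reverse parent links along the path root ... node
    for child in reversed(path[:-1]):
        parent = child.parent
        parent.children.remove(child)
        child.children.append(parent)
        parent.parent = child
        parent.length = child.length
        child.length = 0.0
    node.parent = None
    # collapse old root if it became degree-2
    old_root = path[-1]
    if len(old_root.children) == 1 and old_root is not node:
        only = old_root.children[0]
        gp = old_root.parent
        gp.children[gp.children.index(old_root)] = only
        only.parent = gp
        only.length += old_root.length
    tree.root = node


# ---------------------------------------------------------------------------
# Chain state and engine
# ---------------------------------------------------------------------------

class _ChainState:
    __slots__ = ("tree", "models", "mults", "part_lnl", "ln_prior")

    def __init__(self, tree, models, mults):
        self.tree = tree
        self.models = list(models)
        self.mults = np.asarray(mults, float)
        self.part_lnl = None
        self.ln_prior = None

    def copy(self):
        s = _ChainState(self.tree.copy(), list(self.models), self.mults.copy())
        s.part_lnl = None if self.part_lnl is None else self.part_lnl.copy()
        s.ln_prior = self.ln_prior
        return s

    @property
    def lnL(self):
        return float(self.part_lnl.sum())


class _Engine:
    """Holds compressed data and implements one-generation Metropolis updates."""

    def __init__(self, matrix: CharacterMatrix, scheme: PartitionScheme | None,
                 constraints: ConstraintSet | None, cfg: McmcConfig,
                 models=None):
        self.cfg = cfg
        self.constraints = constraints
        if constraints is not None:
            constraints.validate_taxa(matrix.taxa)
        self.taxa = matrix.taxa
        self.is_morph = matrix.alphabet == "standard"
        if scheme is None:
            scheme = PartitionScheme.single(matrix.n_chars)
        scheme.validate_covers(matrix.n_chars)
        self.part_names = scheme.names
        self.tipdata, self.weights, self.nsites = [], [], []
        self.morph_groups = []  # per partition: [(r, tipdata, weights, n)]
        for name in self.part_names:
            idx = scheme.indices(name)
            td, w = compress_patterns(matrix, idx)
            self.tipdata.append(td)
            self.weights.append(w)
            self.nsites.append(int(w.sum()))
            if self.is_morph:
                self.morph_groups.append(self._group_by_state_count(matrix, idx))
        self.specs = []
        self.init_models = []
        for pi, name in enumerate(self.part_names):
            if models is not None:
                m = models[pi] if isinstance(models, (list, tuple)) else models
                self.init_models.append(m)
                self.specs.append(_spec_of(m))
            else:
                spec = scheme.model(name) or ("Mk" if self.is_morph else "HKY+G")
                n_states = len(matrix.states) if self.is_morph else 4
                self.init_models.append(parse_model(spec, n_states=n_states))
                self.specs.append(spec.upper())
        self.r = len(matrix.states) if self.is_morph else 4
        self.variable_coding = self.is_morph and all(
            getattr(m, "variable_coding", False) for m in self.init_models)
        self._start_hint = self._nj_start(matrix)

    # -- likelihood --------------------------------------------------------
    @staticmethod
    def _group_by_state_count(matrix: CharacterMatrix, idx):
        """Split morphological characters by observed state count; each group
        gets its own Mk state space (binary characters are Mk2, etc.)."""
        from .core import GAP, MISSING
        by_r: dict = {}
        for j in idx:
            obs = set()
            for c in matrix.column(j):
                if c not in (GAP, MISSING):
                    obs |= c
            r = max(len(obs), 2)
            by_r.setdefault(r, []).append((j, sorted(obs)))
        groups = []
        for r, chars in sorted(by_r.items()):
            seen: dict = {}
            weights = []
            tips = []
            for j, states in chars:
                while len(states) < r:
                    states.append(f"_pad{len(states)}")
                key = tuple(tuple(sorted(c)) if isinstance(c, frozenset) else c
                            for c in matrix.column(j))
                if key in seen:
                    weights[seen[key]] += 1.0
                    continue
                seen[key] = len(tips)
                weights.append(1.0)
                col = np.zeros((matrix.n_taxa, r))
                for ti, cell in enumerate(matrix.column(j)):
                    if cell in (GAP, MISSING):
                        col[ti, :] = 1.0
                    else:
                        for s in cell:
                            col[ti, states.index(s)] = 1.0
                tips.append(col)
            tipdata = np.stack(tips, axis=1)  # (n_taxa, n_patterns, r)
            groups.append((r, tipdata, np.asarray(weights), len(chars)))
        return groups

    def part_loglik(self, state: _ChainState, pi: int) -> float:
        model = state.models[pi]
        if self.is_morph and isinstance(model, MkModel):
            total = 0.0
            for r, tipdata, weights, n_chars in self.morph_groups[pi]:
                sub = MkModel(r=r, variable_coding=model.variable_coding,
                              alpha=model.alpha, ncat=model.ncat)
                ll = _site_logliks(state.tree, sub, tipdata, self.taxa,
                                   length_scale=state.mults[pi]) @ weights
                if model.variable_coding:
                    const = np.zeros((len(self.taxa), r, r))
                    for s in range(r):
                        const[:, s, s] = 1.0
                    cll = _site_logliks(state.tree, sub, const, self.taxa,
                                        length_scale=state.mults[pi])
                    p_const = float(np.exp(cll).sum())
                    if p_const >= 1.0:
                        return -np.inf
                    ll -= n_chars * math.log1p(-p_const)
                total += float(ll)
            return total
        return float(_site_logliks(state.tree, model, self.tipdata[pi],
                                   self.taxa, length_scale=state.mults[pi])
                     @ self.weights[pi])

    def full_lnl(self, state: _ChainState) -> None:
        state.part_lnl = np.array([self.part_loglik(state, pi)
                                   for pi in range(len(self.part_names))])
        state.ln_prior = self.ln_prior(state)

    def ln_prior(self, state: _ChainState) -> float:
        rate = self.cfg.brlen_prior_rate
        lp = 0.0
        for n in state.tree.postorder():
            if n is not state.tree.root:
                lp += math.log(rate) - rate * n.length
        for m in state.models:
            if isinstance(m, SubstitutionModel):
                if m.family == "HKY":
                    z = math.log(m.kappa)
                    lp += -0.5 * ((z - 1.0) / 1.25) ** 2 - z
                if m.ncat:
                    lp += -m.alpha
            elif isinstance(m, MkModel):
                if m.ncat:
                    lp += -m.alpha
        return lp

    # -- initial state -----------------------------------------------------
    def _nj_start(self, matrix: CharacterMatrix) -> Tree | None:
        """Distance-based starting tree (JC-corrected p-distances)."""
        from .geo import DistanceMatrix, nj_tree
        from .models import p_distance
        n = len(self.taxa)
        if n < 4:
            return None
        D = np.zeros((n, n))
        try:
            for i in range(n):
                for j in range(i + 1, n):
                    p = p_distance(matrix.cells[i], matrix.cells[j])
                    if self.is_morph:
                        d = max(p, 1e-4)
                    else:
                        d = (-0.75 * math.log(1 - 4 * min(p, 0.70) / 3)
                             if p > 0 else 1e-4)
                    D[i, j] = D[j, i] = d
            tree = nj_tree(DistanceMatrix(list(self.taxa), D))
        except PhylogeoError:
            return None
        for nd in tree.postorder():
            nd.length = max(nd.length, 1e-4)
        if self.constraints is not None and not satisfies(tree, self.constraints):
            return None
        return tree

    def init_state(self, rng, start_tree: Tree | None = None) -> _ChainState:
        if start_tree is None:
            tree = self._start_hint
            if tree is None:
                tree = random_constrained_tree(self.taxa, self.constraints, rng,
                                               self.cfg.brlen_prior_rate)
            else:
                tree = tree.copy()
        else:
            tree = start_tree.copy()
            if self.constraints is not None and not satisfies(tree, self.constraints):
                raise PhylogeoError("start tree violates the constraint set")
        state = _ChainState(tree, [m for m in self.init_models],
                            np.ones(len(self.part_names)))
        self.full_lnl(state)
        return state

    # -- proposals ---------------------------------------------------------
    def _internal_edges(self, tree: Tree):
        return [n for n in tree.postorder()
                if not n.is_leaf and n is not tree.root]

    def propose_nni(self, state: _ChainState, rng):
        if not self._internal_edges(state.tree):
            return None
        tree = state.tree.copy()
        edges = self._internal_edges(tree)
        c = edges[rng.integers(len(edges))]
        p = c.parent
        _reroot_at(tree, p)
        others = [ch for ch in p.children if ch is not c]
        if not others or not c.children:
            return None
        x = c.children[rng.integers(len(c.children))]
        y = others[rng.integers(len(others))]
        c.children[c.children.index(x)] = y
        p.children[p.children.index(y)] = x
        x.parent, y.parent = p, c
        if self.constraints is not None and not satisfies(tree, self.constraints):
            return None  # hard constraint: zero prior mass outside
        new = _ChainState(tree, state.models, state.mults)
        return new, 0.0, None

    def propose_brlen(self, state: _ChainState, rng):
        tree = state.tree.copy()
        nodes = [n for n in tree.postorder() if n is not tree.root]
        n = nodes[rng.integers(len(nodes))]
        lam = 2.0 * math.log(1.6)
        m = math.exp(lam * (rng.random() - 0.5))
        n.length *= m
        new = _ChainState(tree, state.models, state.mults)
        return new, math.log(m), None

    def propose_params(self, state: _ChainState, rng):
        pi = int(rng.integers(len(self.part_names)))
        model = state.models[pi]
        spec = self.specs[pi]
        logh = 0.0
        if isinstance(model, MkModel):
            if not model.ncat:
                return None
            m = math.exp(1.0 * (rng.random() - 0.5))
            model = MkModel(r=model.r, variable_coding=model.variable_coding,
                            alpha=model.alpha * m, ncat=model.ncat)
            logh = math.log(m)
        else:
            choices = []
            if model.family in ("HKY", "GTR"):
                choices.append("freqs")
            if model.family == "HKY":
                choices.append("kappa")
            if model.family == "GTR":
                choices.append("rates")
            if model.ncat:
                choices.append("alpha")
            if "+I" in spec:
                choices.append("pinv")
            if not choices:
                return None
            what = choices[rng.integers(len(choices))]
            kw = dict(family=model.family, freqs=model.freqs, kappa=model.kappa,
                      rates=model.rates, p_inv=model.p_inv, alpha=model.alpha,
                      ncat=model.ncat)
            if what in ("kappa", "alpha"):
                m = math.exp(1.0 * (rng.random() - 0.5))
                kw[{"kappa": "kappa", "alpha": "alpha"}[what]] = \
                    getattr(model, what) * m
                logh = math.log(m)
            elif what == "pinv":
                delta = 0.1 * (rng.random() - 0.5)
                p = model.p_inv + delta
                # reflect into [0, 0.99]
                if p < 0:
                    p = -p
                if p > 0.99:
                    p = 1.98 - p
                kw["p_inv"] = min(max(p, 0.0), 0.99)
            elif what in ("freqs", "rates"):
                cur = np.asarray(getattr(model, what), float)
                cur = cur / cur.sum()
                conc = 300.0
                a_fwd = np.maximum(conc * cur, 1e-3)
                new = rng.dirichlet(a_fwd)
                new = np.maximum(new, 1e-6)
                new = new / new.sum()
                a_rev = np.maximum(conc * new, 1e-3)
                logh = (dirichlet_dist.logpdf(cur, a_rev)
                        - dirichlet_dist.logpdf(new, a_fwd))
                if what == "rates":
                    new = new / new[-1]  # back to GT = 1 convention
                kw[what] = tuple(new)
            model = SubstitutionModel(**kw)
        models = list(state.models)
        models[pi] = model
        new = _ChainState(state.tree, models, state.mults)
        return new, logh, pi

    def step(self, state: _ChainState, beta_heat: float, power: float, rng):
        """One Metropolis update; returns (state, accepted flag)."""
        w = self.cfg.proposal_weights
        kinds, probs = zip(*w.items())
        kind = kinds[int(rng.choice(len(kinds), p=np.asarray(probs) / sum(probs)))]
        if kind == "topology":
            prop = self.propose_nni(state, rng)
        elif kind == "brlen":
            prop = self.propose_brlen(state, rng)
        else:
            prop = self.propose_params(state, rng)
        if prop is None:
            return state, False
        new, logh, only_part = prop
        if only_part is None:
            self.full_lnl(new)
        else:
            new.part_lnl = state.part_lnl.copy()
            new.part_lnl[only_part] = self.part_loglik(new, only_part)
            new.ln_prior = self.ln_prior(new)
        if not np.isfinite(new.lnL):
            return state, False
        log_ratio = beta_heat * (power * (new.lnL - state.lnL)
                                 + (new.ln_prior - state.ln_prior)) + logh
        if log_ratio >= 0 or rng.random() < math.exp(max(log_ratio, -700)):
            return new, True
        return state, False


def _spec_of(model) -> str:
    if isinstance(model, MkModel):
        s = "MKV" if model.variable_coding else "MK"
    else:
        s = model.family
        if model.p_inv > 0:
            s += "+I"
    if model.ncat:
        s += "+G"
    return s


def _params_snapshot(state: _ChainState) -> dict:
    out = {"tree_length": state.tree.total_length()}
    for i, m in enumerate(state.models):
        tag = f"p{i}"
        if isinstance(m, SubstitutionModel):
            out[f"{tag}.kappa"] = m.kappa
            out[f"{tag}.p_inv"] = m.p_inv
            out[f"{tag}.alpha"] = m.alpha if m.ncat else None
            out[f"{tag}.freqs"] = m.freqs
        else:
            out[f"{tag}.alpha"] = m.alpha if m.ncat else None
    return out


# ---------------------------------------------------------------------------
# Public driver: MCMC
# ---------------------------------------------------------------------------

def run_mcmc(matrix: CharacterMatrix, scheme: PartitionScheme | None = None,
             constraints: ConstraintSet | None = None,
             cfg: McmcConfig | None = None, models=None,
             start_tree: Tree | None = None) -> PosteriorSample:
    """Metropolis-coupled MCMC over constraint-satisfying topologies.

    Returns post-burn-in cold-chain samples from every independent run.
    """
    cfg = cfg or McmcConfig()
    engine = _Engine(matrix, scheme, constraints, cfg, models)
    runs = []
    heats = [1.0 / (1.0 + cfg.heat_lambda * c) for c in range(cfg.n_chains)]
    for run_i in range(cfg.n_runs):
        rng = np.random.default_rng((cfg.seed, 17 + run_i))
        chains = [engine.init_state(rng, start_tree) for _ in heats]
        trace = RunTrace()
        accepted_topo = 0
        for gen in range(1, cfg.generations + 1):
            for ci, beta in enumerate(heats):
                chains[ci], acc = engine.step(chains[ci], beta, 1.0, rng)
                if acc and ci == 0:
                    accepted_topo += 1
            if len(heats) > 1 and gen % cfg.swap_interval == 0:
                i = int(rng.integers(len(heats) - 1))
                a, b = chains[i], chains[i + 1]
                post_a = a.lnL + a.ln_prior
                post_b = b.lnL + b.ln_prior
                if math.log(max(rng.random(), 1e-300)) < \
                        (heats[i] - heats[i + 1]) * (post_b - post_a):
                    chains[i], chains[i + 1] = b, a
            if gen % cfg.sample_interval == 0:
                cold = chains[0]
                trace.generations.append(gen)
                trace.trees.append(cold.tree.copy())
                trace.lnL.append(cold.lnL)
                trace.lnPrior.append(cold.ln_prior)
                trace.params.append(_params_snapshot(cold))
        runs.append(trace)
    sample = PosteriorSample(runs, cfg.burnin_fraction, constraints)
    if constraints is not None:
        for t in sample.trees:
            assert satisfies(t, constraints)
    return sample


# ---------------------------------------------------------------------------
# Convergence: SDSF
# ---------------------------------------------------------------------------

def sdsf(samples, min_freq: float = 0.10) -> float:
    """Average SD of split frequencies across independent runs.

    ``samples`` is a list of tree lists, a list of PosteriorSample objects
    (their pooled post-burn-in trees each count as one run), or one
    PosteriorSample with >= 2 runs.
    """
    if isinstance(samples, PosteriorSample):
        runs = [r.post_burnin(samples.burnin_fraction)[0] for r in samples.runs]
    else:
        runs = []
        for s in samples:
            if isinstance(s, PosteriorSample):
                runs.append(s.trees)
            else:
                runs.append(list(s))
    if len(runs) < 2:
        raise PhylogeoError("sdsf needs >= 2 runs")
    if any(len(r) == 0 for r in runs):
        raise PhylogeoError("sdsf: empty sample in at least one run")
    freqs = []
    for trees in runs:
        counts: dict = {}
        for t in trees:
            for s in bipartitions(t):
                counts[s] = counts.get(s, 0) + 1
        n = len(trees)
        freqs.append({s: c / n for s, c in counts.items()})
    splits = {s for f in freqs for s, v in f.items() if v >= min_freq}
    if not splits:
        return 0.0
    sds = []
    for s in splits:
        vals = np.array([f.get(s, 0.0) for f in freqs])
        sds.append(vals.std())  # population SD across runs
    return float(np.mean(sds))


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

def _splits_compatible(a: frozenset, b: frozenset, taxa: frozenset) -> bool:
    return (not (a & b)) or a <= b or b <= a or (a | b) == taxa


def consensus(sample, kind: str = "all-compatible") -> Tree:
    """Greedy extended majority-rule consensus with posterior-probability labels.

    Splits are added in decreasing frequency order while compatible with the
    splits already accepted; node supports are the split frequencies and
    branch lengths are means over the trees containing each split.
    """
    if kind not in ("all-compatible", "majority"):
        raise ValueError(f"unknown consensus kind {kind!r}")
    trees = sample.trees if isinstance(sample, PosteriorSample) else list(sample)
    if not trees:
        raise PhylogeoError("empty sample for consensus")
    taxa = frozenset(trees[0].leaf_labels())
    n = len(trees)
    counts: dict = {}
    blens: dict = {}
    pend: dict = {t: 0.0 for t in taxa}
    for t in trees:
        leafsets = t.edge_leafsets()
        lens = [x.length for x in t.postorder() if x is not t.root]
        per_tree: dict = {}
        for side, ln in zip(leafsets, lens):
            if len(side) == 1:
                pend[next(iter(side))] += ln / n
                continue
            if len(side) == len(taxa) - 1:
                # complement of a pendant edge (rooted storage): same edge
                pend[next(iter(taxa - side))] += ln / n
                continue
            s = normalize_split(side, taxa)
            # a rooted tree's two root children induce the same split; merge
            per_tree[s] = per_tree.get(s, 0.0) + ln
        for s, ln in per_tree.items():
            counts[s] = counts.get(s, 0) + 1
            blens[s] = blens.get(s, 0.0) + ln
    ranked = sorted(counts.items(),
                    key=lambda kv: (-kv[1], len(kv[0]), tuple(sorted(kv[0]))))
    accepted: dict = {}
    for s, c in ranked:
        freq = c / n
        if kind == "majority" and freq <= 0.5:
            break
        if all(_splits_compatible(s, o, taxa) for o in accepted):
            accepted[s] = freq
    # Build a tree from the laminar family of clades. Splits are already
    # normalized to the side not containing the lexicographically first
    # taxon, so they nest under the full taxon set with that taxon at the root.
    root = TreeNode()
    node_of = {frozenset(taxa): root}
    for s in sorted(accepted, key=len, reverse=True):
        best = frozenset(taxa)
        for p in node_of:
            if s < p and len(p) < len(best):
                best = p
        nd = TreeNode(length=blens[s] / counts[s])
        nd.support = accepted[s]
        node_of[best].add_child(nd)
        node_of[s] = nd
    for t in sorted(taxa):
        best = frozenset(taxa)
        for p in node_of:
            if t in p and len(p) < len(best):
                best = p
        node_of[best].add_child(TreeNode(label=t, length=pend[t]))
    return Tree(root, rooted=False)


# ---------------------------------------------------------------------------
# Stepping-stone marginal likelihood
# ---------------------------------------------------------------------------

def _beta_schedule(steps: int, alpha: float) -> np.ndarray:
    j = np.arange(steps, -1, -1)
    return (j / steps) ** (1.0 / alpha)


def _step_contribution(lnls: np.ndarray, d: float) -> float:
    """log( c_upper / c_lower ) from samples at the lower beta.

    ``d = beta_upper - beta_lower > 0``; E_lower[L^d] = c_upper / c_lower,
    estimated stably by factoring out the maximum log-likelihood.
    """
    mx = lnls.max()
    return math.log(np.mean(np.exp(d * (lnls - mx)))) + d * mx


def _block_bootstrap_se(per_step_lnls, ds, rng, reps: int = 100) -> float:
    var_total = 0.0
    for lnls, d in zip(per_step_lnls, ds):
        n = len(lnls)
        block = max(1, n // 10)
        nblocks = math.ceil(n / block)
        vals = np.empty(reps)
        for r in range(reps):
            starts = rng.integers(0, n, size=nblocks)
            idx = (starts[:, None] + np.arange(block)[None, :]).ravel() % n
            vals[r] = _step_contribution(lnls[idx[:n]], d)
        var_total += vals.var()
    return math.sqrt(var_total)


def stepping_stone_generic(loglik_fn, kernel, init_state, steps: int,
                           n_per_step: int, seed: int = 0, alpha: float = 0.3,
                           burnin: int = 0, thin: int = 1) -> MarginalLikelihood:
    """Generic stepping-stone estimator.

    ``kernel(state, beta, rng) -> state`` performs one MCMC update targeting
    prior x L^beta; ``loglik_fn(state)`` returns the data log-likelihood.
    The chain walks from the posterior (beta=1) down to the prior (beta=0);
    each interval's normalizing-constant ratio is estimated from the samples
    at its lower power, with the preceding step acting as that step's
    burn-in (the initial posterior-power run is pure burn-in).
    """
    rng = np.random.default_rng((seed, 9001))
    betas = _beta_schedule(steps, alpha)  # betas[0]=1 ... betas[-1]=0
    state = init_state
    for _ in range(burnin):
        state = kernel(state, 1.0, rng)
    contributions = []
    per_step_lnls = []
    ds = []
    for k in range(1, steps + 1):
        b_hi, b_lo = betas[k - 1], betas[k]
        lnls = np.empty(n_per_step)
        for i in range(n_per_step):
            for _ in range(thin):
                state = kernel(state, b_lo, rng)
            ll = loglik_fn(state)
            if not np.isfinite(ll) and b_lo > 0:
                raise PhylogeoError(
                    f"non-finite likelihood at step {k} (beta={b_lo})")
            lnls[i] = ll
        d = b_hi - b_lo
        contributions.append(_step_contribution(lnls, d))
        per_step_lnls.append(lnls)
        ds.append(d)
    contributions = np.asarray(contributions)
    se = _block_bootstrap_se(per_step_lnls, ds, rng)
    return MarginalLikelihood(float(contributions.sum()), contributions,
                              betas, se)


def stepping_stone(matrix: CharacterMatrix, scheme: PartitionScheme | None = None,
                   constraints: ConstraintSet | None = None,
                   steps: int | None = None, cfg: McmcConfig | None = None,
                   models=None, start_tree: Tree | None = None,
                   data_id: str | None = None) -> MarginalLikelihood:
    """Stepping-stone log marginal likelihood of the constrained model."""
    cfg = cfg or McmcConfig()
    steps = steps or cfg.ss_steps
    engine = _Engine(matrix, scheme, constraints, cfg, models)
    rng0 = np.random.default_rng((cfg.seed, 7777))
    init = engine.init_state(rng0, start_tree)

    def kernel(state, beta, rng):
        new, _ = engine.step(state, 1.0, beta, rng)
        return new

    ml = stepping_stone_generic(
        lambda s: s.lnL, kernel, init, steps=steps,
        n_per_step=max(cfg.ss_generations_per_step, 4),
        seed=cfg.seed, alpha=cfg.ss_alpha, thin=max(cfg.ss_thin, 1),
        burnin=max(cfg.ss_generations_per_step * cfg.ss_thin, 50))
    ml.data_id = data_id
    return ml


# ---------------------------------------------------------------------------
# Bayes factors
# ---------------------------------------------------------------------------

_KASS_RAFTERY = [(2.0, "none"), (6.0, "positive"), (10.0, "strong"),
                 (math.inf, "very strong")]


def bayes_factor(a: MarginalLikelihood, b: MarginalLikelihood,
                 scale: str = "2dln") -> BayesFactor:
    """Compare two marginal likelihoods on the Kass-Raftery 2*delta-ln scale."""
    if a.data_id is not None and b.data_id is not None and a.data_id != b.data_id:
        raise PhylogeoError(
            f"marginal likelihoods computed on different data: "
            f"{a.data_id!r} vs {b.data_id!r}")
    d = a.log_ml - b.log_ml
    two = 2.0 * d
    mag = abs(two)
    for cut, name in _KASS_RAFTERY:
        if mag < cut or math.isinf(cut):
            cat = name
            break
    if mag == 0:
        cat = "none"
    return BayesFactor(delta_ln=d, two_delta_ln=two, category=cat, scale=scale)
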