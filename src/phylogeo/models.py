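"""Substitution models and likelihood machinery.

Implements time-reversible nucleotide models (JC, HKY, GTR) with +I and
discrete-Γ rate variation, the symmetric Mk model for discrete morphology with
the "variable" ascertainment correction (Mkv), Felsenstein pruning with
per-site scaling, Fitch/Hartigan parsimony lengths, character classification,
p-distances, and per-partition BIC model selection.

Rate matrices are scaled so the mean substitution rate at stationarity equals
one, making branch lengths expected substitutions per site. +I+Γ is a
(k+1)-component rate mixture: an invariant category of rate 0 and weight
``p_inv`` plus k equal-weight Γ categories whose rates average 1.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize
from scipy.special import gammainc, logsumexp
from scipy.stats import gamma as gamma_dist

from .core import GAP, MISSING, CharacterMatrix, PhylogeoError, Tree

__all__ = [
    "SubstitutionModel",
    "MkModel",
    "parse_model",
    "discrete_gamma_rates",
    "transition_probabilities",
    "rate_categories",
    "loglik",
    "loglik_mkv",
    "fitch_length",
    "classify_characters",
    "p_distance",
    "bic_select",
    "BicResult",
]


# ---------------------------------------------------------------------------
# Model definitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubstitutionModel:
    """Reversible nucleotide model; family JC, HKY or GTR."""

    family: str = "JC"
    freqs: tuple = (0.25, 0.25, 0.25, 0.25)  # pi_A, pi_C, pi_G, pi_T
    kappa: float = 1.0                        # HKY transition/transversion rate ratio
    # GTR exchangeabilities (AC, AG, AT, CG, CT, GT); GT fixed to 1 by convention
    rates: tuple = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    p_inv: float = 0.0
    alpha: float = 1.0
    ncat: int = 0  # 0 disables the gamma mixture

    def __post_init__(self):
        f = np.asarray(self.freqs, float)
        if f.shape != (4,) or abs(f.sum() - 1) > 1e-8 or (f <= 0).any():
            raise ValueError("freqs must be a positive 4-simplex")
        if not 0 <= self.p_inv < 1:
            raise ValueError("p_inv must lie in [0, 1)")
        if self.alpha <= 0:
            raise ValueError("gamma shape alpha must be positive")
        if self.family not in ("JC", "HKY", "GTR"):
            raise ValueError(f"unknown family {self.family!r}")

    @property
    def n_states(self):
        return 4

    def Q(self) -> np.ndarray:
        """Rate matrix scaled to mean rate 1 at stationarity."""
        pi = np.asarray(self.freqs, float)
        if self.family == "JC":
            pi = np.full(4, 0.25)
            ex = np.ones((4, 4))
        elif self.family == "HKY":
            ex = np.ones((4, 4))
            # transitions: A<->G (0,2), C<->T (1,3)
            ex[0, 2] = ex[2, 0] = ex[1, 3] = ex[3, 1] = self.kappa
        else:
            r = self.rates
            ex = np.array([
                [0, r[0], r[1], r[2]],
                [r[0], 0, r[3], r[4]],
                [r[1], r[3], 0, r[5]],
                [r[2], r[4], r[5], 0],
            ], float)
        Q = ex * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(pi * np.diag(Q)).sum()
        return Q / mu

    def stationary(self) -> np.ndarray:
        if self.family == "JC":
            return np.full(4, 0.25)
        return np.asarray(self.freqs, float)


@dataclass(frozen=True)
class MkModel:
    """Symmetric k-state model for discrete morphology; uniform stationary freqs."""

    r: int = 2
    variable_coding: bool = True
    alpha: float = 1.0
    ncat: int = 0
    p_inv: float = 0.0  # unused in practice for morphology; kept for symmetry

    def __post_init__(self):
        if self.r < 2:
            raise ValueError("state count r must be >= 2")
        if self.alpha <= 0:
            raise ValueError("gamma shape alpha must be positive")

    @property
    def n_states(self):
        return self.r

    def Q(self) -> np.ndarray:
        r = self.r
        Q = np.full((r, r), 1.0 / (r - 1))
        np.fill_diagonal(Q, -1.0)
        return Q

    def stationary(self) -> np.ndarray:
        return np.full(self.r, 1.0 / self.r)


_MODEL_RE = re.compile(r"^(JC|JC69|HKY|HKY85|GTR|MKV?|MK)((?:\+[IG])*)$", re.I)


def parse_model(spec: str, n_states: int = 2, ncat: int = 4) -> SubstitutionModel | MkModel:
    """Parse a model spec string such as ``"GTR+I+G"`` or ``"Mk+G"`` (case-insensitive)."""
    m = _MODEL_RE.match(spec.strip().replace(" ", ""))
    if not m:
        raise ValueError(f"cannot parse model spec {spec!r}")
    fam = m.group(1).upper()
    flags = m.group(2).upper()
    has_i, has_g = "+I" in flags, "+G" in flags
    if fam in ("MK", "MKV"):
        return MkModel(r=n_states, variable_coding=True,
                       ncat=ncat if has_g else 0)
    fam = {"JC69": "JC", "HKY85": "HKY"}.get(fam, fam)
    return SubstitutionModel(family=fam, p_inv=0.1 if has_i else 0.0,
                             ncat=ncat if has_g else 0)


# ---------------------------------------------------------------------------
# Rates and transition probabilities
# ---------------------------------------------------------------------------

def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Mean-per-equal-probability-bin discretization of Gamma(alpha, mean 1).

    Returns k category rates with equal probability 1/k, renormalized so their
    average is exactly 1.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return np.array([1.0])
    # Gamma with shape a and rate a has mean 1; bin boundaries at quantiles i/k.
    edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), a=alpha, scale=1.0 / alpha)
    edges[0], edges[-1] = 0.0, np.inf
    # E[X; X in (lo, hi)] = P(a+1, hi*a) - P(a+1, lo*a) for mean-1 gamma
    upper = gammainc(alpha + 1, np.where(np.isinf(edges), np.inf, edges * alpha))
    rates = (upper[1:] - upper[:-1]) * k
    return rates / rates.mean()


_rate_cat_cache: dict = {}


def rate_categories(model) -> tuple[np.ndarray, np.ndarray]:
    """Mixture (weights, rates) for the model's +I/+Γ configuration."""
    key = (type(model).__name__, model.ncat, model.alpha, model.p_inv)
    hit = _rate_cat_cache.get(key)
    if hit is not None:
        return hit
    if model.ncat and model.ncat > 1:
        g = discrete_gamma_rates(model.alpha, model.ncat)
    else:
        g = np.array([1.0])
    w = np.full(len(g), (1.0 - model.p_inv) / len(g))
    if model.p_inv > 0:
        out = (np.concatenate([[model.p_inv], w]), np.concatenate([[0.0], g]))
    else:
        out = (w, g)
    _rate_cat_cache[key] = out
    if len(_rate_cat_cache) > 512:
        _rate_cat_cache.pop(next(iter(_rate_cat_cache)))
    return out


_decomp_cache: dict = {}


def _decompose(model):
    key = model
    hit = _decomp_cache.get(key)
    if hit is not None:
        return hit
    Q = model.Q()
    pi = model.stationary()
    sq = np.sqrt(pi)
    B = (Q / sq[None, :]) * sq[:, None]  # D^1/2 Q D^-1/2, symmetric for reversible Q
    B = (B + B.T) / 2
    lam, V = np.linalg.eigh(B)
    left = V.T * sq[None, :]        # V' diag(sqrt pi)
    right = V / sq[:, None]         # diag(1/sqrt pi) V
    _decomp_cache[key] = (lam, right, left)
    if len(_decomp_cache) > 256:
        _decomp_cache.pop(next(iter(_decomp_cache)))
    return lam, right, left


def transition_probabilities(model, t: float) -> np.ndarray:
    """Row-stochastic matrix exp(Qt) via eigendecomposition of the symmetrized Q."""
    if t < 0:
        raise ValueError("branch length must be non-negative")
    if t == 0:
        return np.eye(model.n_states)
    lam, right, left = _decompose(model)
    P = (right * np.exp(lam * t)[None, :]) @ left
    np.maximum(P, 0.0, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


# ---------------------------------------------------------------------------
# Pruning likelihood
# ---------------------------------------------------------------------------

def _tip_partials(cell, states) -> np.ndarray:
    n = len(states)
    if cell in (GAP, MISSING):
        return np.ones(n)
    v = np.zeros(n)
    for s in cell:
        v[states.index(s)] = 1.0
    if not v.any():
        raise PhylogeoError(f"cell {cell!r} has no state in alphabet {states}")
    return v


def _postorder_arrays(tree: Tree):
    """Postorder node list with child index lists and branch lengths."""
    nodes = list(tree.postorder())
    index = {id(n): i for i, n in enumerate(nodes)}
    children = [[index[id(c)] for c in n.children] for n in nodes]
    lengths = np.array([n.length for n in nodes])
    leaf_ids = {n.label: index[id(n)] for n in nodes if n.is_leaf}
    return nodes, children, lengths, leaf_ids


def _site_logliks(tree: Tree, model, tipdata: np.ndarray, taxa,
                  length_scale: float = 1.0) -> np.ndarray:
    """Per-site log-likelihood under the model's full rate mixture.

    tipdata: array (n_taxa, n_sites, n_states) of tip partial likelihoods,
    rows aligned with ``taxa``. ``length_scale`` multiplies every branch
    length (used for per-partition rate multipliers).
    """
    nodes, children, lengths, leaf_ids = _postorder_arrays(tree)
    missing = [t for t in taxa if t not in leaf_ids]
    if missing:
        raise PhylogeoError(f"taxa absent from tree: {missing}")
    n_nodes = len(nodes)
    n_sites = tipdata.shape[1]
    ns = model.n_states
    pi = model.stationary()
    weights, rates = rate_categories(model)

    per_cat = np.empty((len(rates), n_sites))
    for ci, rate in enumerate(rates):
        partial = np.empty((n_nodes, n_sites, ns))
        logscale = np.zeros(n_sites)
        for ti, t in enumerate(taxa):
            partial[leaf_ids[t]] = tipdata[ti]
        for i, kids in enumerate(children):
            if not kids:
                continue
            acc = np.ones((n_sites, ns))
            for k in kids:
                P = transition_probabilities(model, rates[ci] * lengths[k] * length_scale) \
                    if rate > 0 else np.eye(ns)
                acc *= partial[k] @ P.T
            mx = acc.max(axis=1)
            mx[mx == 0] = 1.0
            acc /= mx[:, None]
            logscale += np.log(mx)
            partial[i] = acc
        root_like = partial[len(nodes) - 1] @ pi
        with np.errstate(divide="ignore"):
            per_cat[ci] = np.log(root_like) + logscale
    if len(rates) == 1:
        return per_cat[0] + np.log(weights[0])
    return logsumexp(per_cat, axis=0, b=weights[:, None])


def _matrix_tipdata(matrix: CharacterMatrix, site_indices=None) -> np.ndarray:
    idx = range(matrix.n_chars) if site_indices is None else site_indices
    states = list(matrix.states)
    arr = np.empty((matrix.n_taxa, len(list(idx)), len(states)))
    idx = list(range(matrix.n_chars)) if site_indices is None else list(site_indices)
    for ti, row in enumerate(matrix.cells):
        for sj, j in enumerate(idx):
            arr[ti, sj] = _tip_partials(row[j], states)
    return arr


def loglik(tree: Tree, model, matrix: CharacterMatrix,
           site_indices=None, site_weights=None) -> float:
    """Total log-likelihood by Felsenstein pruning over the +I/+Γ mixture."""
    tipdata = _matrix_tipdata(matrix, site_indices)
    site_ll = _site_logliks(tree, model, tipdata, matrix.taxa)
    if site_weights is not None:
        return float(site_ll @ np.asarray(site_weights, float))
    return float(site_ll.sum())


def compress_patterns(matrix: CharacterMatrix, site_indices=None):
    """Collapse identical site patterns; returns (unique tipdata, weights)."""
    idx = list(range(matrix.n_chars)) if site_indices is None else list(site_indices)
    seen: dict = {}
    order = []
    weights = []
    for j in idx:
        key = tuple(row[j] for row in matrix.cells)
        if key in seen:
            weights[seen[key]] += 1.0
        else:
            seen[key] = len(order)
            order.append(j)
            weights.append(1.0)
    tipdata = _matrix_tipdata(matrix, order)
    return tipdata, np.array(weights)


def loglik_mkv(tree: Tree, model: MkModel, matrix: CharacterMatrix) -> float:
    """Mk log-likelihood with the "variable" ascertainment correction.

    Each character's likelihood is divided by the probability of being
    variable, 1 - sum_s P(constant pattern s), with the rate mixture applied
    inside both numerator and correction.
    """
    states = list(matrix.states)
    if len(states) > model.r:
        raise PhylogeoError(
            f"matrix has {len(states)} states but Mk model has r={model.r}")
    for j in range(matrix.n_chars):
        obs = set()
        for c in matrix.column(j):
            if c not in (GAP, MISSING):
                obs |= c
        if len(obs) > model.r:
            raise PhylogeoError(
                f"character {j + 1} shows {len(obs)} states > model r={model.r}")
    # pad matrix state space up to r
    full_states = states + [f"_pad{i}" for i in range(model.r - len(states))]
    tipdata = np.zeros((matrix.n_taxa, matrix.n_chars, model.r))
    for ti, row in enumerate(matrix.cells):
        for j, cell in enumerate(row):
            if cell in (GAP, MISSING):
                tipdata[ti, j, :] = 1.0
            else:
                for s in cell:
                    tipdata[ti, j, full_states.index(s)] = 1.0
    site_ll = _site_logliks(tree, model, tipdata, matrix.taxa)
    if not model.variable_coding:
        return float(site_ll.sum())
    # constant patterns: one pseudo-site per state
    const = np.zeros((matrix.n_taxa, model.r, model.r))
    for s in range(model.r):
        const[:, s, s] = 1.0
    const_ll = _site_logliks(tree, model, const, matrix.taxa)
    p_const = np.exp(const_ll).sum()
    if p_const >= 1.0:
        return -np.inf
    return float(site_ll.sum() - matrix.n_chars * np.log1p(-p_const))


# ---------------------------------------------------------------------------
# Parsimony utilities
# ---------------------------------------------------------------------------

def fitch_length(tree: Tree, column, taxa) -> int:
    """Minimum state changes on the tree (Hartigan's generalization: handles
    polytomies and ambiguity/missing by state-set union)."""
    obs = set()
    for c in column:
        if c not in (GAP, MISSING):
            obs |= c
    if len(obs) <= 1:
        return 0
    full = frozenset(obs)
    cell_of = dict(zip(taxa, column))
    cost = 0
    sets: dict = {}
    for n in tree.postorder():
        if n.is_leaf:
            c = cell_of.get(n.label, MISSING)
            sets[id(n)] = full if c in (GAP, MISSING) else frozenset(c & obs) or full
        else:
            counts: dict = {}
            for ch in n.children:
                for s in sets[id(ch)]:
                    counts[s] = counts.get(s, 0) + 1
            kmax = max(counts.values())
            sets[id(n)] = frozenset(s for s, k in counts.items() if k == kmax)
            cost += len(n.children) - kmax
    return cost


def classify_characters(matrix: CharacterMatrix) -> list[str]:
    """Per-character class: constant / variable-uninformative / parsimony-informative.

    Ambiguous and missing cells are excluded from the state counts.
    """
    out = []
    for j in range(matrix.n_chars):
        counts: dict = {}
        for c in matrix.column(j):
            if c in (GAP, MISSING) or len(c) != 1:
                continue
            s = next(iter(c))
            counts[s] = counts.get(s, 0) + 1
        if len(counts) <= 1:
            out.append("constant")
        elif sum(1 for k in counts.values() if k >= 2) >= 2:
            out.append("parsimony-informative")
        else:
            out.append("variable-uninformative")
    return out


def p_distance(a, b, as_percent: bool = False) -> float:
    """Uncorrected proportion of differing sites; gap/missing/ambiguous excluded."""
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    diff = comp = 0
    for x, y in zip(a, b):
        if x in (GAP, MISSING) or y in (GAP, MISSING):
            continue
        if len(x) != 1 or len(y) != 1:
            continue
        comp += 1
        if x != y:
            diff += 1
    if comp == 0:
        raise PhylogeoError("no comparable sites between sequences")
    p = diff / comp
    return 100.0 * p if as_percent else p


# ---------------------------------------------------------------------------
# BIC model selection
# ---------------------------------------------------------------------------

_K_BASE = {"JC": 0, "HKY": 4, "GTR": 8}


def _free_params(spec: str) -> int:
    fam = spec.split("+")[0].upper()
    k = _K_BASE[{"JC69": "JC", "HKY85": "HKY"}.get(fam, fam)]
    if "+I" in spec.upper():
        k += 1
    if "+G" in spec.upper():
        k += 1
    return k


def _pack(model: SubstitutionModel, spec: str, scale: float) -> np.ndarray:
    x = [np.log(scale)]
    fam = model.family
    if fam in ("HKY", "GTR"):
        f = np.asarray(model.freqs)
        x.extend(np.log(f[:3] / f[3]))
    if fam == "HKY":
        x.append(np.log(model.kappa))
    elif fam == "GTR":
        x.extend(np.log(np.asarray(model.rates[:5]) / model.rates[5]))
    if "+I" in spec.upper():
        p = min(max(model.p_inv, 1e-4), 0.999)
        x.append(np.log(p / (1 - p)))
    if "+G" in spec.upper():
        x.append(np.log(model.alpha))
    return np.array(x)


def _unpack(x: np.ndarray, spec: str, ncat: int):
    fam = spec.split("+")[0].upper()
    fam = {"JC69": "JC", "HKY85": "HKY"}.get(fam, fam)
    i = 0
    scale = float(np.exp(np.clip(x[i], -8, 8)))
    i += 1
    kw = {"family": fam}
    if fam in ("HKY", "GTR"):
        raw = np.exp(np.clip(x[i:i + 3], -12, 12))
        i += 3
        f = np.append(raw, 1.0)
        kw["freqs"] = tuple(f / f.sum())
    if fam == "HKY":
        kw["kappa"] = float(np.exp(np.clip(x[i], -8, 8)))
        i += 1
    elif fam == "GTR":
        r = np.exp(np.clip(x[i:i + 5], -10, 10))
        i += 5
        kw["rates"] = tuple(np.append(r, 1.0))
    if "+I" in spec.upper():
        kw["p_inv"] = float(1 / (1 + np.exp(-np.clip(x[i], -12, 12)))) * 0.999
        i += 1
    if "+G" in spec.upper():
        kw["alpha"] = float(np.exp(np.clip(x[i], -5, 6)))
        kw["ncat"] = ncat
        i += 1
    return SubstitutionModel(**kw), scale


@dataclass
class BicResult:
    best: str
    best_model: SubstitutionModel
    table: "object"  # pandas DataFrame

    def to_tsv(self, path):
        self.table.to_csv(path, sep="\t", index=False)


def _scaled_tree(tree: Tree, scale: float) -> Tree:
    t = tree.copy()
    for n in t.postorder():
        n.length *= scale
    return t


def bic_select(tree: Tree, matrix: CharacterMatrix, candidates,
               site_indices=None, ncat: int = 4) -> BicResult:
    """Per-partition model selection by BIC on a fixed reference tree.

    All candidates share one free tree-length scale (not counted in K).
    Nested candidates are warm-started from simpler fits so added parameters
    never reduce the maximized log-likelihood.
    """
    import pandas as pd

    if not candidates:
        raise ValueError("candidate list is empty")
    tipdata, weights = compress_patterns(matrix, site_indices)
    n_sites = int(weights.sum())
    taxa = matrix.taxa

    def negll(x, spec):
        try:
            model, scale = _unpack(x, spec, ncat)
        except (ValueError, FloatingPointError):
            return 1e12
        t = _scaled_tree(tree, scale)
        ll = _site_logliks(t, model, tipdata, taxa) @ weights
        if not np.isfinite(ll):
            return 1e12
        return -float(ll)

    # empirical frequencies for initialization
    counts = np.zeros(4)
    for row in matrix.cells:
        for c in row:
            if isinstance(c, frozenset) and len(c) == 1:
                counts["ACGT".index(next(iter(c)))] += 1
    emp = (counts + 1) / (counts + 1).sum()

    fits: dict = {}
    rows = []
    order = sorted(set(candidates), key=_free_params)
    for spec in order:
        fam = spec.split("+")[0].upper()
        fam = {"JC69": "JC", "HKY85": "HKY"}.get(fam, fam)
        init = SubstitutionModel(
            family=fam,
            freqs=tuple(emp) if fam != "JC" else (0.25,) * 4,
            kappa=2.0, p_inv=0.1 if "+I" in spec.upper() else 0.0,
            alpha=1.0, ncat=ncat if "+G" in spec.upper() else 0)
        starts = [_pack(init, spec, 1.0)]
        # warm start from the best already-fit nested candidate
        for prev_spec, (prev_m, prev_scale, prev_ll) in fits.items():
            if _is_nested(prev_spec, spec):
                warm = replace(
                    prev_m, family=fam,
                    freqs=prev_m.freqs if prev_m.family != "JC" else tuple(emp),
                    rates=_promote_rates(prev_m),
                    p_inv=prev_m.p_inv if "+I" in spec.upper() and prev_m.p_inv > 0 else
                          (0.05 if "+I" in spec.upper() else 0.0),
                    alpha=prev_m.alpha,
                    ncat=ncat if "+G" in spec.upper() else 0)
                starts.append(_pack(warm, spec, prev_scale))
        best = None
        converged = True
        for x0 in starts:
            res = optimize.minimize(negll, x0, args=(spec,), method="L-BFGS-B",
                                    options={"maxiter": 300})
            if best is None or res.fun < best.fun:
                best = res
        converged = bool(best.success or best.fun < 1e11)
        model, scale = _unpack(best.x, spec, ncat)
        ll = -best.fun
        fits[spec] = (model, scale, ll)
        K = _free_params(spec)
        rows.append({"model": spec, "lnL": ll, "K": K,
                     "BIC": -2 * ll + K * np.log(n_sites),
                     "converged": converged})
    table = pd.DataFrame(rows).sort_values("BIC").reset_index(drop=True)
    best_spec = table.iloc[0]["model"]
    return BicResult(best=best_spec, best_model=fits[best_spec][0], table=table)


def _is_nested(small: str, big: str) -> bool:
    fam_order = {"JC": 0, "HKY": 1, "GTR": 2}
    fs = small.split("+")[0].upper()
    fb = big.split("+")[0].upper()
    fs = {"JC69": "JC", "HKY85": "HKY"}.get(fs, fs)
    fb = {"JC69": "JC", "HKY85": "HKY"}.get(fb, fb)
    if fam_order[fs] > fam_order[fb]:
        return False
    for flag in ("+I", "+G"):
        if flag in small.upper() and flag not in big.upper():
            return False
    return True


def _promote_rates(m: SubstitutionModel) -> tuple:
    if m.family == "GTR":
        return m.rates
    if m.family == "HKY":
        k = m.kappa
        return (1.0, k, 1.0, 1.0, k, 1.0)
    return (1.0,) * 6
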