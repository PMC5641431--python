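"""Stochastic character mapping and homoplasy quantification.

Maps discrete morphological characters onto a (molecular) tree by sampling
explicit substitution histories conditional on tip states under a symmetric
Mk model: an upward pruning pass, joint node-state sampling on the way down,
then endpoint-conditioned branch histories by uniformization. Summaries per
character are the posterior-mean number of transformations, the consistency
index CI = m / s (m = observed distinct states - 1, the parsimony minimum for
an unordered character; s = mean mapped changes), the homoplasy index
HI = 1 - CI, and per-state dwell-time fractions. Characters are aggregated
into anatomical regions of the gonopod (coxa, prefemur, tibiotarsus) to give
each region's share of overall homoplasy.

Rate uncertainty is handled by a per-character rate scaler with a gamma
prior, integrated over a discrete grid posterior.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .core import GAP, MISSING, CharacterMatrix, PhylogeoError, Tree
from .models import MkModel, rate_categories, transition_probabilities, \
    fitch_length, _postorder_arrays, _tip_partials

__all__ = [
    "CharacterHistory",
    "HomoplasyReport",
    "sample_history",
    "consistency_index",
    "dwell_times",
    "map_characters",
    "region_homoplasy",
    "homoplasy_summary",
    "GONOPOD_REGIONS",
]

GONOPOD_REGIONS = ("coxa", "prefemur", "tibiotarsus")


@dataclass
class CharacterHistory:
    """One sampled substitution history of a character over a tree."""

    events: dict          # postorder node index -> [(time_offset, from, to), ...]
    node_states: np.ndarray
    dwell: np.ndarray     # per-state occupancy time over the whole tree
    total_length: float

    @property
    def n_events(self) -> int:
        return sum(len(v) for v in self.events.values())


# ---------------------------------------------------------------------------
# Endpoint-conditioned path sampling (uniformization)
# ---------------------------------------------------------------------------

def _uniformized_path(Q: np.ndarray, t: float, a: int, b: int, rng,
                      max_n: int = 500):
    """Sample a CTMC path on (0, t) conditional on endpoints a -> b.

    Returns a list of (time, from_state, to_state) real transitions.
    """
    r = Q.shape[0]
    if t <= 0:
        if a != b:
            raise PhylogeoError("zero-length branch with differing endpoints")
        return []
    omega = 1.05 * max(-Q[i, i] for i in range(r))
    if omega <= 0:
        return []
    R = np.eye(r) + Q / omega
    pois_mean = omega * t
    # P(N = n | a, b) proportional to Poisson(omega t)(n) * R^n[a, b]
    powers = [np.eye(r)]
    log_pois = -pois_mean
    total = 0.0
    n = 0
    u = rng.random()
    probs = []
    # accumulate until the normalizer is effectively complete
    while n <= max_n:
        w = math.exp(log_pois) * powers[n][a, b]
        probs.append(w)
        total += w
        if n > pois_mean and w < 1e-14 * max(total, 1e-300):
            break
        if pois_mean == 0:
            break
        n += 1
        powers.append(powers[-1] @ R)
        log_pois += math.log(pois_mean) - math.log(n)
    if total <= 0:
        raise PhylogeoError(
            f"endpoint-conditioned sampling failed (a={a}, b={b}, t={t})")
    cum = 0.0
    N = len(probs) - 1
    for i, w in enumerate(probs):
        cum += w
        if u * total <= cum:
            N = i
            break
    # jump-chain states given N jumps
    states = [a]
    for i in range(1, N):
        back = powers[N - i]
        p = R[states[-1], :] * back[:, b]
        s = p.sum()
        if s <= 0:
            raise PhylogeoError("inconsistent jump-chain state probabilities")
        states.append(int(rng.choice(len(p), p=p / s)))
    if N >= 1:
        states.append(b)
    times = np.sort(rng.random(N)) * t
    path = []
    for tm, s0, s1 in zip(times, states[:-1], states[1:]):
        if s0 != s1:
            path.append((float(tm), int(s0), int(s1)))
    return path


def _conditional_partials(tree: Tree, model: MkModel, cell_of, states,
                          rate: float):
    nodes, children, lengths, leaf_ids = _postorder_arrays(tree)
    r = model.r
    Q = model.Q() * rate
    partial = np.ones((len(nodes), r))
    log_scale = 0.0
    for i, node in enumerate(nodes):
        if node.is_leaf:
            cell = cell_of.get(node.label, MISSING)
            if cell in (GAP, MISSING):
                partial[i] = 1.0
            else:
                v = np.zeros(r)
                for s in cell:
                    v[states.index(s)] = 1.0
                partial[i] = v
        else:
            for k in children[i]:
                P = transition_probabilities(model, rate * lengths[k])
                partial[i] *= P @ partial[k]
            mx = partial[i].max()
            if mx > 0:
                partial[i] /= mx
                log_scale += math.log(mx)
    return nodes, children, lengths, partial, Q, log_scale


def sample_history(tree: Tree, model: MkModel, column, taxa, n_draws: int,
                   seed: int = 0, rate: float = 1.0) -> list:
    """Sample ``n_draws`` substitution histories conditional on the tip states.

    When the model carries a Γ mixture, a rate category is drawn per history
    from its posterior given the data, and the branch histories are sampled at
    that category's rate times ``rate``.
    """
    rng = np.random.default_rng((seed, 4242))
    states = _observed_states(column)
    if not states:
        raise PhylogeoError("character has no observed state")
    while len(states) < model.r:
        states.append(f"_s{len(states)}")
    cell_of = dict(zip(taxa, column))
    weights, cat_rates = rate_categories(model)
    # posterior over rate categories given the tips
    cat_lls = []
    cache = {}
    for cr in cat_rates:
        eff = rate * cr
        nodes, children, lengths, partial, Q, log_scale = _conditional_partials(
            tree, model, cell_of, states, max(eff, 1e-12))
        root_like = float(partial[-1] @ model.stationary())
        cat_lls.append(math.log(max(root_like, 1e-300)) + log_scale)
        parent_of = {}
        for p, kids in enumerate(children):
            for k in kids:
                parent_of[k] = p
        cache[cr] = (nodes, children, lengths, partial, Q, log_scale, parent_of)
    post = np.asarray(weights) * np.exp(np.asarray(cat_lls) - max(cat_lls))
    post = post / post.sum()
    total_len = tree.total_length()
    out = []
    for _ in range(n_draws):
        cr = cat_rates[int(rng.choice(len(cat_rates), p=post))]
        eff = max(rate * cr, 1e-12)
        nodes, children, lengths, partial, Q, _ls, parent_of = cache[cr]
        n_nodes = len(nodes)
        node_state = np.empty(n_nodes, dtype=int)
        # root draw
        p = model.stationary() * partial[-1]
        node_state[-1] = int(rng.choice(model.r, p=p / p.sum()))
        events: dict = {}
        dwell = np.zeros(model.r)
        # preorder: parents have higher postorder index than children
        for i in range(n_nodes - 2, -1, -1):
            a = node_state[parent_of[i]]
            P = transition_probabilities(model, eff * lengths[i])
            p = P[a, :] * partial[i]
            node_state[i] = int(rng.choice(model.r, p=p / p.sum()))
            path = _uniformized_path(Q, lengths[i], a, node_state[i], rng)
            if path:
                events[i] = path
            # occupancy along this branch
            cur = a
            last_t = 0.0
            for tm, s0, s1 in path:
                dwell[cur] += tm - last_t
                cur, last_t = s1, tm
            dwell[cur] += lengths[i] - last_t
        out.append(CharacterHistory(events, node_state, dwell, total_len))
    return out


def _observed_states(column) -> list:
    obs = set()
    for c in column:
        if c not in (GAP, MISSING):
            obs |= c
    return sorted(obs)


# ---------------------------------------------------------------------------
# Per-character summaries
# ---------------------------------------------------------------------------

def consistency_index(histories, tree: Tree, column, taxa):
    """(CI, HI) from sampled histories; (None, None) for a constant character.

    CI = m / s with m = observed distinct states - 1 (the parsimony minimum
    for an unordered character) and s the mean mapped change count, clipped
    at 1 against Monte-Carlo noise.
    """
    if not histories:
        raise PhylogeoError("need at least one sampled history")
    m = len(_observed_states(column)) - 1
    if m == 0:
        return None, None
    s = float(np.mean([h.n_events for h in histories]))
    ci = min(m / s, 1.0) if s > 0 else 1.0
    return ci, 1.0 - ci


def dwell_times(histories) -> np.ndarray:
    """Mean per-state fraction of total tree time; fractions sum to 1."""
    if not histories:
        raise PhylogeoError("need at least one sampled history")
    fr = np.mean([h.dwell / h.total_length for h in histories], axis=0)
    return fr / fr.sum()


# ---------------------------------------------------------------------------
# Whole-matrix mapping
# ---------------------------------------------------------------------------

@dataclass
class HomoplasyReport:
    """Per-character homoplasy summaries plus anatomical-region aggregates."""

    characters: list = field(default_factory=list)  # list of dicts

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.characters)

    def to_tsv(self, path):
        df = self.to_frame().copy()
        df["dwell"] = df["dwell"].apply(
            lambda v: ",".join(f"{x:.4f}" for x in v) if v is not None else "")
        df.to_csv(path, sep="\t", index=False)

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.characters, fh, indent=1, default=_jsonable)

    def applicable(self, regions=None):
        rows = [c for c in self.characters if c["ci"] is not None]
        if regions is not None:
            rows = [c for c in rows if c["region"] in regions]
        return rows


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return [float(v) for v in x]
    if isinstance(x, (np.floating, np.integer)):
        return float(x)
    raise TypeError(type(x))


def map_characters(tree: Tree, matrix: CharacterMatrix, n_draws: int = 100,
                   seed: int = 0, ncat: int = 0, rate_prior_shape: float = 1.25,
                   rate_grid: np.ndarray | None = None) -> HomoplasyReport:
    """Stochastic-map every character of a morphology matrix onto a tree.

    A per-character rate scaler with a Gamma(rate_prior_shape, mean 1) prior
    is integrated over a log-spaced grid: each history draw first samples the
    scaler from its grid posterior given the character, then samples node
    states and branch histories at that rate.
    """
    if rate_grid is None:
        rate_grid = np.geomspace(0.05, 20.0, 21)
    prior = (rate_grid ** (rate_prior_shape - 1)
             * np.exp(-rate_prior_shape * rate_grid))
    if len(rate_grid) > 1:
        prior = prior * np.gradient(rate_grid)  # trapezoid-style grid weights
    report = HomoplasyReport()
    for j in range(matrix.n_chars):
        column = matrix.column(j)
        obs = _observed_states(column)
        meta = matrix.char_meta[j]
        if len(obs) <= 1:
            report.characters.append({
                "char": j, "region": meta.get("region", "other"),
                "states": len(obs), "min_changes": 0, "mean_changes": 0.0,
                "ci": None, "hi": None, "dwell": None})
            continue
        model = MkModel(r=len(obs), ncat=ncat)
        # grid posterior of the rate scaler
        lls = np.empty(len(rate_grid))
        cell_of = dict(zip(matrix.taxa, column))
        for gi, r in enumerate(rate_grid):
            _, _, _, partial, _, log_scale = _conditional_partials(
                tree, model, cell_of, obs, r)
            lls[gi] = math.log(max(float(partial[-1] @ model.stationary()),
                                   1e-300)) + log_scale
        w = prior * np.exp(lls - lls.max())
        w = w / w.sum()
        rng = np.random.default_rng((seed, 31, j))
        counts = rng.multinomial(n_draws, w)
        histories = []
        for gi, k in enumerate(counts):
            if k:
                histories.extend(sample_history(
                    tree, model, column, matrix.taxa, int(k),
                    seed=int(rng.integers(2**31)), rate=float(rate_grid[gi])))
        ci, hi = consistency_index(histories, tree, column, matrix.taxa)
        report.characters.append({
            "char": j, "region": meta.get("region", "other"),
            "states": len(obs),
            "min_changes": fitch_length(tree, column, matrix.taxa),
            "mean_changes": float(np.mean([h.n_events for h in histories])),
            "ci": ci, "hi": hi,
            "dwell": dwell_times(histories)})
    return report


# ---------------------------------------------------------------------------
# Region aggregation and summaries
# ---------------------------------------------------------------------------

def region_homoplasy(report: HomoplasyReport, regions=GONOPOD_REGIONS,
                     statistic: str = "hi") -> dict:
    """Per-region share of overall gonopodal homoplasy.

    ``statistic="hi"`` (default) divides each region's summed HI by the total
    over the included regions; ``"ci"`` aggregates CI instead (both published
    conventions are available).
    """
    if statistic not in ("hi", "ci"):
        raise ValueError("statistic must be 'hi' or 'ci'")
    sums = {r: 0.0 for r in regions}
    for c in report.applicable(regions):
        sums[c["region"]] += c[statistic]
    total = sum(sums.values())
    if total == 0:
        return {r: 0.0 for r in regions}
    shares = {r: v / total for r, v in sums.items()}
    for r, v in sums.items():
        if v == 0.0:
            import warnings
            warnings.warn(f"region {r!r} has no applicable characters")
    return shares


def homoplasy_summary(report: HomoplasyReport, threshold: float = 0.5,
                      regions=GONOPOD_REGIONS) -> float:
    """Fraction of applicable region-tagged characters with HI above threshold."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    rows = report.applicable(regions)
    if not rows:
        return 0.0
    return sum(1 for c in rows if c["hi"] > threshold) / len(rows)
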