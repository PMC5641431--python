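"""Synthetic data with controlled signal: Yule trees, partitioned sequences,
morphology with a tunable convergence fraction, and geography whose spatial
proximity tracks the phylogeny with tunable noise.

The generator's defaults mirror the study system it emulates: 90 taxa, a
six-partition 3,975-bp nucleotide supermatrix under GTR/HKY-family models,
68 discrete morphological characters (46 binary, 22 multistate; 40 tagged to
the three gonopod regions), and locality clouds produced by Brownian
dispersal along the tree. Tests and the acceptance analyses pass smaller
explicit sizes.

Convergent morphology is created by evolving a fraction rho of characters on
a single shared decoy tree drawn independently of the true tree: those
characters carry clean synapomorphies for the wrong topology, the known-truth
analogue of convergent gonopod evolution.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .core import CharacterMatrix, PartitionScheme, Tree, TreeNode
from .engine import random_constrained_tree  # noqa: F401  (re-export convenience)
from .geo import LocalityRecord, RegionMap
from .models import MkModel, SubstitutionModel, parse_model, rate_categories, \
    transition_probabilities

__all__ = [
    "SimConfig",
    "simulate_yule_tree",
    "simulate_sequences",
    "simulate_morphology",
    "simulate_localities",
    "simulate_dataset",
]


@dataclass
class SimConfig:
    n_taxa: int = 90
    birth_rate: float = 1.0
    tree_height: float = 1.0          # expected substitutions, root to tip
    partition_lengths: tuple = (663, 662, 662, 663, 662, 663)  # 3,975 bp total
    partition_models: tuple = ("GTR+I+G", "GTR+I+G", "GTR+I+G",
                               "HKY+I", "GTR+I+G", "HKY+I")
    n_morph_chars: int = 68
    binary_fraction: float = 46 / 68
    convergence_fraction: float = 0.0  # rho
    morph_rate: float = 1.0
    # gamma shape for per-character rate multipliers (None = equal rates)
    morph_rate_alpha: float | None = None
    gonopod_fraction: float = 40 / 68
    region_weights: tuple = (1 / 3, 1 / 3, 1 / 3)  # coxa, prefemur, tibiotarsus
    dispersal_sigma_km: float = 100.0
    geo_noise: float = 0.0
    max_localities: int = 3
    jitter_km: float = 5.0
    origin: tuple = (37.5, -81.0)     # southern Appalachians
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.convergence_fraction <= 1:
            raise ValueError("convergence fraction must lie in [0, 1]")
        if not 0 <= self.geo_noise <= 1:
            raise ValueError("geo noise must lie in [0, 1]")
        if self.n_taxa < 3 or self.n_morph_chars < 1:
            raise ValueError("counts must be positive (n_taxa >= 3)")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def simulate_yule_tree(n: int, birth_rate: float = 1.0, seed: int = 0,
                       height: float = 1.0) -> Tree:
    """Ultrametric Yule tree with n tips, rescaled to the target root height."""
    if n < 3:
        raise ValueError("need n >= 3 taxa")
    rng = np.random.default_rng((seed, 101))
    root = TreeNode()
    tips = []
    for _ in range(2):
        c = TreeNode()
        root.add_child(c)
        tips.append(c)
    birth_time = {id(root): 0.0, id(tips[0]): 0.0, id(tips[1]): 0.0}
    t = 0.0
    k = 2
    while k < n:
        t += rng.exponential(1.0 / (birth_rate * k))
        tip = tips.pop(rng.integers(len(tips)))
        birth = birth_time[id(tip)]
        tip.length = t - birth
        for _ in range(2):
            c = TreeNode()
            tip.add_child(c)
            birth_time[id(c)] = t
            tips.append(c)
        k += 1
    t += rng.exponential(1.0 / (birth_rate * n))
    for i, tip in enumerate(tips):
        tip.length = t - birth_time[id(tip)]
    for i, tip in enumerate(tips):
        tip.label = f"t{i + 1:03d}"
    tree = Tree(root, rooted=True)
    scale = height / t
    for node in tree.postorder():
        node.length *= scale
    return tree


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

def _evolve_states(tree: Tree, P_of, root_probs, n_sites: int, rng):
    """Simulate site states down the tree; returns {leaf label: int array}."""
    nstates = len(root_probs)
    states = {id(tree.root): rng.choice(nstates, size=n_sites, p=root_probs)}
    out = {}
    for node in tree.preorder():
        if node is tree.root:
            pass
        else:
            P = P_of(node.length)
            cum = P.cumsum(axis=1)
            parent = states[id(node.parent)]
            u = rng.random(n_sites)
            states[id(node)] = (u[:, None] > cum[parent]).sum(axis=1)
        if node.is_leaf:
            out[node.label] = states[id(node)]
    return out


def simulate_sequences(tree: Tree, scheme: PartitionScheme | None = None,
                       models=None, seed: int = 0,
                       n_sites: int | None = None) -> CharacterMatrix:
    """Partitioned DNA simulation under the given models (mean rate 1)."""
    rng = np.random.default_rng((seed, 211))
    if scheme is None:
        scheme = PartitionScheme.single(n_sites or 1000, model="HKY+G")
    names = scheme.names
    if models is None:
        models = [parse_model(scheme.model(nm) or "JC") for nm in names]
    elif not isinstance(models, (list, tuple)):
        models = [models] * len(names)
    total = max(max(idx) for nm in names for idx in [scheme.indices(nm)]) + 1
    taxa = tree.leaf_labels()
    cols: dict = {}
    for nm, model in zip(names, models):
        idx = scheme.indices(nm)
        weights, rates = rate_categories(model)
        cats = rng.choice(len(rates), size=len(idx), p=weights)
        pi = model.stationary()
        seqs = {t: np.empty(len(idx), dtype=int) for t in taxa}
        for ci, rate in enumerate(rates):
            sel = np.where(cats == ci)[0]
            if len(sel) == 0:
                continue
            if rate == 0:
                base = rng.choice(4, size=len(sel), p=pi)
                for t in taxa:
                    seqs[t][sel] = base
            else:
                leaf_states = _evolve_states(
                    tree,
                    lambda L, r=rate: transition_probabilities(model, r * L),
                    pi, len(sel), rng)
                for t in taxa:
                    seqs[t][sel] = leaf_states[t]
        for k, j in enumerate(idx):
            cols[j] = {t: seqs[t][k] for t in taxa}
    sym = "ACGT"
    cells = [[frozenset(sym[cols[j][t]]) for j in range(total)] for t in taxa]
    meta = [{"partition": None, "region": "other"} for _ in range(total)]
    for nm in names:
        for j in scheme.indices(nm):
            meta[j]["partition"] = nm
    return CharacterMatrix(taxa, cells, "dna", char_meta=meta)


# ---------------------------------------------------------------------------
# Morphology with controlled convergence
# ---------------------------------------------------------------------------

def simulate_morphology(tree: Tree, cfg: SimConfig, seed: int | None = None):
    """Discrete characters; a fraction rho evolves on a shared decoy tree.

    Constant characters are redrawn (the matrix is "variable"-coded).
    Returns (matrix, truth) where truth records each character's generating
    tree ("true" or "decoy") and the decoy tree itself.
    """
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng((seed, 307))
    taxa = tree.leaf_labels()
    decoy = simulate_yule_tree(len(taxa), cfg.birth_rate,
                               seed=int(rng.integers(2**31)),
                               height=cfg.tree_height)
    # decoy leaves get a random permutation of the taxon labels
    perm = list(taxa)
    rng.shuffle(perm)
    for leaf, lab in zip(decoy.leaves(), perm):
        leaf.label = lab
    regions = ("coxa", "prefemur", "tibiotarsus")
    cells = {t: [] for t in taxa}
    truth_src = []
    metas = []
    n_conv = int(round(cfg.convergence_fraction * cfg.n_morph_chars))
    for j in range(cfg.n_morph_chars):
        on_decoy = j < n_conv
        gen_tree = decoy if on_decoy else tree
        r = 2 if rng.random() < cfg.binary_fraction else int(rng.integers(3, 5))
        model = MkModel(r=r)
        for _ in range(1000):
            char_rate = cfg.morph_rate
            if cfg.morph_rate_alpha is not None:
                a = cfg.morph_rate_alpha
                char_rate *= rng.gamma(a, 1.0 / a)
            P_of = lambda L: transition_probabilities(model, char_rate * L)
            states = _evolve_states(gen_tree, P_of, model.stationary(), 1, rng)
            vals = {t: int(states[t][0]) for t in taxa}
            if len(set(vals.values())) > 1:
                break
        else:
            raise RuntimeError("could not draw a variable character; "
                               "increase morph_rate")
        for t in taxa:
            cells[t].append(frozenset(str(vals[t])))
        if rng.random() < cfg.gonopod_fraction:
            region = regions[rng.choice(3, p=np.asarray(cfg.region_weights))]
        else:
            region = "somatic"
        metas.append({"partition": "morphology", "region": region})
        truth_src.append("decoy" if on_decoy else "true")
    states_all = tuple(sorted({s for t in taxa for c in cells[t] for s in c}))
    matrix = CharacterMatrix(taxa, [cells[t] for t in taxa], "standard",
                             states=states_all, char_meta=metas)
    truth = {"rho": cfg.convergence_fraction, "generating_tree": truth_src,
             "decoy_newick": decoy.newick()}
    return matrix, truth


# ---------------------------------------------------------------------------
# Geography
# ---------------------------------------------------------------------------

_KM_PER_DEG = 111.194927  # mean-radius km per degree of latitude


def simulate_localities(tree: Tree, sigma_km: float, noise: float = 0.0,
                        regions: RegionMap | None = None, seed: int = 0,
                        max_localities: int = 3, jitter_km: float = 5.0,
                        origin=(37.5, -81.0)) -> list:
    """Brownian dispersal of (x, y) km positions along the tree.

    Each tip receives 1..max_localities records jittered around its position;
    with probability ``noise`` a tip's position is redrawn uniformly over the
    occupied bounding box (destroying its phylogenetic signal).
    """
    if sigma_km <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng((seed, 401))
    pos = {id(tree.root): np.zeros(2)}
    tip_pos = {}
    for node in tree.preorder():
        if node is not tree.root:
            step = rng.normal(0.0, sigma_km * math.sqrt(max(node.length, 0.0)),
                              size=2)
            pos[id(node)] = pos[id(node.parent)] + step
        if node.is_leaf:
            tip_pos[node.label] = pos[id(node)]
    xs = np.array([p[0] for p in tip_pos.values()])
    ys = np.array([p[1] for p in tip_pos.values()])
    span = max(np.ptp(xs), np.ptp(ys), 4 * sigma_km)
    for t in tip_pos:
        if rng.random() < noise:
            tip_pos[t] = np.array([
                rng.uniform(xs.min() - 0.1 * span, xs.min() + 1.1 * span),
                rng.uniform(ys.min() - 0.1 * span, ys.min() + 1.1 * span)])
    lat0, lon0 = origin
    records = []
    for t in sorted(tip_pos):
        k = int(rng.integers(1, max_localities + 1))
        for _ in range(k):
            xy = tip_pos[t] + rng.normal(0.0, jitter_km, size=2)
            lat = lat0 + xy[1] / _KM_PER_DEG
            lon = lon0 + xy[0] / (_KM_PER_DEG * math.cos(math.radians(lat0)))
            records.append(LocalityRecord(t, float(np.clip(lat, -89.9, 89.9)),
                                          float(((lon + 180) % 360) - 180)))
    return records


# ---------------------------------------------------------------------------
# Whole datasets
# ---------------------------------------------------------------------------

def simulate_dataset(cfg: SimConfig) -> dict:
    """Simulate a full study bundle: tree, sequences, morphology, localities."""
    tree = simulate_yule_tree(cfg.n_taxa, cfg.birth_rate, cfg.seed,
                              cfg.tree_height)
    scheme = _scheme_from_cfg(cfg)
    seqs = simulate_sequences(tree, scheme,
                              [parse_model(m) for m in cfg.partition_models],
                              seed=cfg.seed)
    morph, truth = simulate_morphology(tree, cfg)
    records = simulate_localities(tree, cfg.dispersal_sigma_km, cfg.geo_noise,
                                  seed=cfg.seed,
                                  max_localities=cfg.max_localities,
                                  jitter_km=cfg.jitter_km, origin=cfg.origin)
    return {"tree": tree, "scheme": scheme, "sequences": seqs,
            "morphology": morph, "localities": records, "truth": truth}


def _scheme_from_cfg(cfg: SimConfig) -> PartitionScheme:
    parts = {}
    start = 0
    for i, (ln, model) in enumerate(zip(cfg.partition_lengths,
                                        cfg.partition_models)):
        parts[f"gene{i + 1}"] = (tuple(range(start, start + ln)), model)
        start += ln
    return PartitionScheme(parts)


def write_dataset(bundle: dict, outdir) -> None:
    """Write the bundle in the same formats the pipeline reads, plus a truth file."""
    import os
    os.makedirs(outdir, exist_ok=True)
    from .geo import write_localities
    bundle["sequences"].write_fasta(os.path.join(outdir, "sequences.fasta"))
    bundle["morphology"].write_nexus(os.path.join(outdir, "morphology.nex"))
    with open(os.path.join(outdir, "true_tree.nwk"), "w") as fh:
        fh.write(bundle["tree"].newick() + "\n")
    write_localities(bundle["localities"], os.path.join(outdir, "localities.csv"))
    scheme = bundle["scheme"]
    with open(os.path.join(outdir, "partitions.txt"), "w") as fh:
        for nm in scheme.names:
            idx = scheme.indices(nm)
            model = scheme.model(nm)
            suffix = f" ; model={model}" if model else ""
            fh.write(f"{nm} = {idx[0] + 1}-{idx[-1] + 1}{suffix}\n")
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump({"true_newick": bundle["tree"].newick(),
                   **bundle["truth"]}, fh, indent=1)
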