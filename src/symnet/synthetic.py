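"""Synthetic tripartite communities with known ground truth.

Emulates a field survey of aphid species, the parasitoids attacking them,
the plants they feed on and the facultative-symbiont strains they carry:
each species has one dominant parasitoid (most attacks), mostly one
dominant plant, and a handful of dominant symbiont strains.  The strength
of coupling between strain sharing and parasitoid sharing, phylogeny, or
plant sharing is tunable, so parameter-recovery and type-I-error
behaviour of the downstream matrix regressions can be measured against a
known truth.  Marker sequences are evolved along a random birth (Yule)
tree so phylogenetic distance matrices are available without downloads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .observations import NO_ASSOCIATION, ObservationTable
from .otu import SequenceSet

_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticConfig:
    """Generator settings; defaults mirror a 22-species field survey."""

    n_species: int = 22
    seq_len: int = 400
    mutation_rate: float = 0.02  # per site per unit branch length
    n_parasitoids: int = 30
    n_strains: int = 25
    n_plants: int = 20
    dominance: float = 0.8  # attack share of the dominant parasitoid
    coupling_parasitoid: float = 0.0  # strain profile mass tied to parasitoids
    coupling_phylo: float = 0.0  # ... borrowed from nearest relative
    coupling_plant: float = 0.0  # ... tied to the dominant plant's pool
    samples_per_species: int | tuple[int, int] = 40
    noise: float = 0.5  # Dirichlet concentration of the residual strain mass
    no_association_fraction: float = 0.05
    parasitoid_block_size: tuple[int, int] = (1, 3)
    seed: int | None = None

    def __post_init__(self) -> None:
        lam = self.coupling_parasitoid + self.coupling_phylo + self.coupling_plant
        if lam > 1 + 1e-12:
            raise ValueError(
                "coupling_parasitoid + coupling_phylo + coupling_plant must be <= 1"
            )
        if not 0 < self.dominance <= 1:
            raise ValueError("dominance must be in (0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth stored alongside a generated observation table."""

    tree_newick: str
    couplings: dict[str, float]
    dominant_parasitoid: dict[str, str]
    dominant_plant: dict[str, str]
    signature_strain: dict[str, str]  # parasitoid -> its signature strain
    strain_profiles: dict[str, list[float]] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


class _Node:
    __slots__ = ("children", "length", "name")

    def __init__(self, name=None, length=0.0):
        self.children: list[_Node] = []
        self.length = length
        self.name = name

    def newick(self) -> str:
        if not self.children:
            return f"{self.name}:{self.length:.6f}"
        inner = ",".join(c.newick() for c in self.children)
        return f"({inner}):{self.length:.6f}"


def _yule_tree(n: int, rng: np.random.Generator) -> _Node:
    """Pure-birth tree: unit-rate exponential waiting times, random splits."""
    root = _Node()
    tips = [root]
    while len(tips) < n:
        wait = rng.exponential(1.0 / len(tips))
        for t in tips:
            t.length += wait
        k = rng.integers(len(tips))
        parent = tips.pop(k)
        left, right = _Node(), _Node()
        parent.children = [left, right]
        tips += [left, right]
    final = rng.exponential(1.0 / len(tips))
    for t in tips:
        t.length += final
    for i, t in enumerate(tips):
        t.name = f"sp{i + 1:02d}"
    return root


def _evolve(
    node: _Node, seq: np.ndarray, mu: float, rng: np.random.Generator, out: dict
) -> None:
    p_mut = 1.0 - np.exp(-mu * node.length)
    hit = rng.random(len(seq)) < p_mut
    if hit.any():
        seq = seq.copy()
        # substitute to one of the three other bases, uniformly
        shifts = rng.integers(1, 4, size=int(hit.sum()))
        seq[hit] = (seq[hit] + shifts) % 4
    if not node.children:
        out[node.name] = seq
        return
    for child in node.children:
        _evolve(child, seq, mu, rng, out)


def _patristic(root: _Node) -> pd.DataFrame:
    """Tip-to-tip path distances along the tree."""
    dists: dict[tuple[str, str], float] = {}

    def walk(node: _Node) -> dict[str, float]:
        if not node.children:
            return {node.name: node.length}
        below: list[dict[str, float]] = [walk(c) for c in node.children]
        for a in range(len(below)):
            for b in range(a + 1, len(below)):
                for ta, da in below[a].items():
                    for tb, db in below[b].items():
                        dists[(ta, tb)] = dists[(tb, ta)] = da + db
        merged = {t: d + node.length for part in below for t, d in part.items()}
        return merged

    walk(root)
    tips = sorted({t for pair in dists for t in pair})
    D = pd.DataFrame(0.0, index=tips, columns=tips)
    for (a, b), d in dists.items():
        D.at[a, b] = d
    return D


def simulate_sequences(
    n_species: int = 22,
    seq_len: int = 400,
    mutation_rate: float = 0.02,
    seed: int | None = None,
) -> tuple[SequenceSet, str]:
    """Evolve one marker sequence per species along a random Yule tree.

    Returns the aligned sequences and the tree as a newick string.  With
    ``mutation_rate`` 0 all sequences equal the root sequence.
    """
    if n_species < 3:
        raise ValueError("need at least 3 species")
    rng = np.random.default_rng(seed)
    tree = _yule_tree(n_species, rng)
    root_seq = rng.integers(0, 4, size=seq_len)
    out: dict[str, np.ndarray] = {}
    _evolve(tree, root_seq, mutation_rate, rng, out)
    ids = sorted(out)
    seqs = ["".join(_BASES[out[i]]) for i in ids]
    return SequenceSet(ids, seqs, aligned=True), tree.newick() + ";"


def simulate_community(
    config: SyntheticConfig,
) -> tuple[ObservationTable, SyntheticTruth, SequenceSet]:
    """Generate an observation table with known coupling structure.

    Mechanism: each parasitoid carries a signature symbiont strain; a
    species' strain profile mixes (i) its parasitoids' signature strains
    weighted by attack frequency, (ii) its nearest relative's profile,
    (iii) a pool associated with its dominant plant, and (iv) Dirichlet
    noise, with weights (coupling_parasitoid, coupling_phylo,
    coupling_plant, remainder).  Observation records are categorical draws
    from the per-species profiles; a configurable fraction is marked
    'No Association' for parasitoid/strain, emulating screened-but-
    negative samples.

    Returns ``(observations, truth, marker sequences)``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    seqs, newick = simulate_sequences(
        cfg.n_species, cfg.seq_len, cfg.mutation_rate, seed=rng.integers(2**31)
    )
    species = list(seqs.ids)
    parasitoids = [f"wasp{k + 1:02d}" for k in range(cfg.n_parasitoids)]
    strains = [f"H{k + 1:03d}" for k in range(cfg.n_strains)]
    plants = [f"plant{k + 1:02d}" for k in range(cfg.n_plants)]

    # dominant parasitoids assigned in blocks so some are shared across
    # species; blocks run over a shuffled species order so parasitoid
    # sharing is independent of phylogeny unless coupling_phylo says so
    dominant_par: dict[str, str] = {}
    pool = rng.permutation(cfg.n_parasitoids)
    par_order = [species[k] for k in rng.permutation(cfg.n_species)]
    pos, b = 0, 0
    lo, hi = cfg.parasitoid_block_size
    while pos < cfg.n_species:
        size = int(rng.integers(lo, hi + 1))
        par = parasitoids[pool[b % cfg.n_parasitoids]]
        for sp in par_order[pos : pos + size]:
            dominant_par[sp] = par
        pos += size
        b += 1

    # attack profiles: dominance mass on the dominant, rest over 1-3 minors
    attack = pd.DataFrame(0.0, index=species, columns=parasitoids)
    for sp in species:
        attack.at[sp, dominant_par[sp]] = cfg.dominance
        rest = 1.0 - cfg.dominance
        if rest > 0:
            n_minor = int(rng.integers(1, 4))
            others = [p for p in parasitoids if p != dominant_par[sp]]
            minors = rng.choice(others, size=min(n_minor, len(others)), replace=False)
            w = rng.dirichlet(np.ones(len(minors)))
            for p, wk in zip(minors, w):
                attack.at[sp, p] += rest * wk

    # one signature strain per parasitoid (distinct when n_strains allows)
    signature = {
        p: strains[k % cfg.n_strains] for k, p in enumerate(parasitoids)
    }

    # plant profiles: one dominant plant per species, shared in blocks.
    # blocks are formed over an independently shuffled species order so
    # plant sharing is not confounded with parasitoid sharing.
    dominant_plant: dict[str, str] = {}
    plant_pool = rng.permutation(cfg.n_plants)
    plant_order = [species[k] for k in rng.permutation(cfg.n_species)]
    pos, b = 0, 0
    while pos < cfg.n_species:
        size = int(rng.integers(1, 4))
        pl = plants[plant_pool[b % cfg.n_plants]]
        for sp in plant_order[pos : pos + size]:
            dominant_plant[sp] = pl
        pos += size
        b += 1
    plant_profile = pd.DataFrame(0.0, index=species, columns=plants)
    for sp in species:
        plant_profile.at[sp, dominant_plant[sp]] = 0.8
        others = [p for p in plants if p != dominant_plant[sp]]
        minors = rng.choice(others, size=min(2, len(others)), replace=False)
        w = rng.dirichlet(np.ones(len(minors)))
        for p, wk in zip(minors, w):
            plant_profile.at[sp, p] += 0.2 * wk

    # per-plant strain pools for the plant-coupling channel
    plant_strain = {p: strains[int(rng.integers(cfg.n_strains))] for p in plants}

    strain_idx = {s: k for k, s in enumerate(strains)}
    base = np.zeros((cfg.n_species, cfg.n_strains))
    for i, sp in enumerate(species):
        for p in parasitoids:
            w = attack.at[sp, p]
            if w > 0:
                base[i, strain_idx[signature[p]]] += w

    D = patristic_distances(newick)
    nearest = {}
    for sp in species:
        row = D.loc[sp].drop(sp)
        nearest[sp] = row.idxmin()

    lam_par = cfg.coupling_parasitoid
    lam_phy = cfg.coupling_phylo
    lam_pla = cfg.coupling_plant
    resid = 1.0 - lam_par - lam_phy - lam_pla
    profiles = np.zeros_like(base)
    noise = rng.dirichlet(np.full(cfg.n_strains, cfg.noise), size=cfg.n_species)
    for i, sp in enumerate(species):
        prof = lam_par * base[i]
        prof = prof + lam_phy * base[species.index(nearest[sp])]
        pool_vec = np.zeros(cfg.n_strains)
        pool_vec[strain_idx[plant_strain[dominant_plant[sp]]]] = 1.0
        prof = prof + lam_pla * pool_vec
        prof = prof + resid * noise[i]
        profiles[i] = prof / prof.sum()

    # emit observation records
    rows = []
    sid = 0
    locations = [f"site{k + 1:02d}" for k in range(8)]
    for i, sp in enumerate(species):
        if isinstance(cfg.samples_per_species, tuple):
            ns = int(rng.integers(cfg.samples_per_species[0], cfg.samples_per_species[1] + 1))
        else:
            ns = cfg.samples_per_species
        for _ in range(ns):
            sid += 1
            plant = str(rng.choice(plants, p=plant_profile.loc[sp].to_numpy()))
            if rng.random() < cfg.no_association_fraction:
                par = NO_ASSOCIATION
            else:
                par = str(rng.choice(parasitoids, p=attack.loc[sp].to_numpy()))
            if rng.random() < cfg.no_association_fraction:
                strain = NO_ASSOCIATION
            else:
                strain = str(rng.choice(strains, p=profiles[i]))
            rows.append(
                dict(
                    sample_id=f"S{sid:05d}",
                    year=int(rng.choice([2021, 2022])),
                    location=str(rng.choice(locations)),
                    aphid_species=sp,
                    plant_species=plant,
                    parasitoid_species=par,
                    strain_id=strain,
                    source=str(rng.choice(["mummy", "live"], p=[0.8, 0.2])),
                )
            )
    df = pd.DataFrame(rows)
    df["year"] = df["year"].astype("Int64")
    table = ObservationTable(df)
    table.log(f"synthetic community: {cfg.n_species} species, seed={cfg.seed}")
    truth = SyntheticTruth(
        tree_newick=newick,
        couplings=dict(
            parasitoid=lam_par, phylo=lam_phy, plant=lam_pla, residual=resid
        ),
        dominant_parasitoid=dominant_par,
        dominant_plant=dominant_plant,
        signature_strain=signature,
        strain_profiles={sp: profiles[i].tolist() for i, sp in enumerate(species)},
    )
    return table, truth, seqs


def patristic_distances(newick: str) -> pd.DataFrame:
    """Tip-to-tip path distances parsed back from an emitted newick string.

    Handles the binary trees this module writes (every node is either
    ``name:length`` or ``(..,..):length``).
    """
    pos = 0

    def parse() -> _Node:
        nonlocal pos
        node = _Node()
        if newick[pos] == "(":
            pos += 1
            node.children.append(parse())
            while newick[pos] == ",":
                pos += 1
                node.children.append(parse())
            pos += 1  # ')'
        else:
            start = pos
            while newick[pos] not in ":,();":
                pos += 1
            node.name = newick[start:pos]
        if pos < len(newick) and newick[pos] == ":":
            pos += 1
            start = pos
            while newick[pos] not in ",();":
                pos += 1
            node.length = float(newick[start:pos])
        return node

    root = parse()
    return _patristic(root)
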