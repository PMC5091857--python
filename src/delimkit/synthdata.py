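"""Synthetic barcode datasets with known ground truth.

The generator chains the processes the delimitation methods assume: a Yule
(pure-birth) species tree, within-species coalescent genealogies nested in
its branches (the multispecies coalescent, no migration), K2P sequence
evolution along the gene tree, and stochastic availability of morphological
and acoustic differentiability evidence between species.

Time is measured in millions of years by convention; the default
substitution rate of 7.35e-3 substitutions/site/Ma is a published 16S rRNA
clock for hylid frogs, and ``theta`` is the expected coalescence time of a
pair of lineages sampled within one species.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import InputError
from .integrate import EvidenceTable, LineageInfo, PairEvidence
from .seqdist import Alignment, write_fasta
from .trees import TreeNode, UltrametricTree


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for one synthetic dataset.

    Defaults emulate a regional frog-barcoding survey: 8 species, 4
    sequenced specimens each, ~550 bp of 16S, shallow within-species
    variation and species divergences an order of magnitude deeper.
    """

    n_species: int = 8
    speciation_rate: float = 0.2  # events / lineage / Ma
    samples_per_species: int = 4
    theta: float = 0.3  # expected pairwise within-species coalescence time (Ma)
    seq_length: int = 550  # sites
    subst_rate: float = 7.35e-3  # substitutions / site / Ma (16S hylid clock)
    kappa: float = 4.0  # transition/transversion rate ratio
    p_morph: float = 0.7  # P(species pair morphologically differentiable)
    p_acoust: float = 0.7  # P(species pair acoustically differentiable)
    frac_named: float = 0.25  # fraction of species carrying nominal names
    min_species_divergence: Optional[float] = 5.0  # rescale youngest split (Ma)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise InputError("n_species must be >= 1")
        for name in ("speciation_rate", "theta", "subst_rate", "kappa"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")
        for name in ("p_morph", "p_acoust", "frac_named"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name} must be in [0, 1], got {v}")


def sim_yule_tree(
    n_species: int, rate: float, seed: int | np.random.Generator
) -> UltrametricTree:
    """Simulate a Yule species tree with ``n_species`` tips.

    From k lineages the waiting time to the next speciation is exponential
    with rate ``k * rate``; the present is one further exponential waiting
    time after the last split, so terminal branches have positive length.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_species == 1:
        return UltrametricTree(TreeNode(name="sp01", height=0.0))
    if rate <= 0:
        raise InputError("speciation rate must be > 0 for n_species >= 2")
    t = 0.0
    root = TreeNode()
    active = [root]
    event_time: dict[int, float] = {}
    while len(active) < n_species:
        k = len(active)
        t += rng.exponential(1.0 / (k * rate))
        node = active.pop(int(rng.integers(k)))
        event_time[id(node)] = t
        c1, c2 = TreeNode(), TreeNode()
        node.add_child(c1)
        node.add_child(c2)
        active.extend([c1, c2])
    t_end = t + rng.exponential(1.0 / (n_species * rate))
    tree = UltrametricTree(root)
    for node in tree.preorder():
        node.height = 0.0 if node.is_leaf else t_end - event_time[id(node)]
    for i, tip in enumerate(tree.tips(), start=1):
        tip.name = f"sp{i:02d}"
    return tree


def sim_msc_gene_tree(
    species_tree: UltrametricTree,
    samples_per_species: int,
    theta: float,
    seed: int | np.random.Generator,
) -> tuple[UltrametricTree, dict[str, str]]:
    """Multispecies-coalescent gene tree within a species tree.

    Within each species-tree branch, each pair of gene lineages coalesces at
    rate ``1/theta`` (so two samples of one species have expected TMRCA
    ``theta``); lineages that fail to coalesce are handed to the parent
    branch.  Returns the gene tree and the sample-id -> species map.
    """
    if samples_per_species < 1:
        raise InputError("samples_per_species must be >= 1")
    if theta <= 0:
        raise InputError("theta must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    species_map: dict[str, str] = {}
    lineages_at: dict[int, list[TreeNode]] = {}

    def coalesce_in_branch(
        lineages: list[TreeNode], t_bot: float, t_top: float
    ) -> list[TreeNode]:
        lineages = list(lineages)
        t = t_bot
        while len(lineages) >= 2:
            k = len(lineages)
            total_rate = (k * (k - 1) / 2) / theta
            t += rng.exponential(1.0 / total_rate)
            if t >= t_top:
                break
            i, j = sorted(rng.choice(k, size=2, replace=False))
            b = lineages.pop(int(j))
            a = lineages.pop(int(i))
            lineages.append(TreeNode(height=t, children=[a, b]))
        return lineages

    # species-tree nodes processed from the tips upward (ascending height)
    order = {n: i for i, n in enumerate(species_tree.preorder())}
    nodes = sorted(species_tree.preorder(), key=lambda n: (n.height, order[n]))
    for node in nodes:
        if node.is_leaf:
            samples = [
                TreeNode(name=f"{node.name}_{k + 1}", height=0.0)
                for k in range(samples_per_species)
            ]
            for s in samples:
                species_map[s.name] = node.name
            entering = samples
        else:
            entering = []
            for c in node.children:
                entering.extend(lineages_at[id(c)])
        t_top = node.parent.height if node.parent is not None else math.inf
        lineages_at[id(node)] = coalesce_in_branch(entering, node.height, t_top)

    remaining = lineages_at[id(species_tree.root)]
    assert len(remaining) == 1
    return UltrametricTree(remaining[0]), species_map


# base encoding: 0=A 1=C 2=G 3=T; transitions A<->G, C<->T
_BASES = np.array(list("ACGT"))
_TS_PARTNER = np.array([2, 3, 0, 1])
_TV_PARTNERS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])


def _k2p_evolve(
    seq: np.ndarray, dt: float, alpha: float, beta: float, rng: np.random.Generator
) -> np.ndarray:
    """Evolve an encoded sequence for duration ``dt`` under K2P rates."""
    e1 = math.exp(-4.0 * beta * dt)
    e2 = math.exp(-2.0 * (alpha + beta) * dt)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv_each = 0.25 - 0.25 * e1
    u = rng.random(seq.shape[0])
    out = seq.copy()
    ts_mask = u < p_ts
    tv1_mask = (u >= p_ts) & (u < p_ts + p_tv_each)
    tv2_mask = (u >= p_ts + p_tv_each) & (u < p_ts + 2 * p_tv_each)
    out[ts_mask] = _TS_PARTNER[seq[ts_mask]]
    out[tv1_mask] = _TV_PARTNERS[seq[tv1_mask], 0]
    out[tv2_mask] = _TV_PARTNERS[seq[tv2_mask], 1]
    return out


def sim_k2p_sequences(
    gene_tree: UltrametricTree,
    seq_length: int,
    subst_rate: float,
    kappa: float,
    seed: int | np.random.Generator,
) -> Alignment:
    """Evolve sequences along a gene tree under the K2P substitution model.

    ``subst_rate`` is the total substitution rate per site per time unit;
    transitions occur at ``kappa`` times the rate of each transversion.
    """
    if seq_length < 1:
        raise InputError("seq_length must be >= 1")
    if subst_rate < 0 or kappa <= 0:
        raise InputError("subst_rate must be >= 0 and kappa > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    beta = subst_rate / (kappa + 2.0)
    alpha = kappa * beta
    root_seq = rng.integers(0, 4, size=seq_length)
    records: list[tuple[str, str]] = []

    def down(node: TreeNode, seq: np.ndarray) -> None:
        if node.is_leaf:
            records.append((node.name, "".join(_BASES[seq])))
            return
        for c in node.children:
            dt = node.height - c.height
            down(c, _k2p_evolve(seq, dt, alpha, beta, rng))

    down(gene_tree.root, root_seq)
    records.sort(key=lambda r: r[0])
    return Alignment.from_records(records)


def sim_evidence_table(
    species: list[str],
    p_morph: float,
    p_acoust: float,
    frac_named: float,
    seed: int | np.random.Generator,
) -> EvidenceTable:
    """Random differentiability evidence between true species.

    Each unordered species pair is independently morphologically (resp.
    acoustically) differentiable with probability ``p_morph`` (``p_acoust``);
    the complement is an explicit "no".  A seeded fraction of species carry
    nominal names.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    species = sorted(species)
    n_named = int(round(frac_named * len(species)))
    named = set(
        rng.choice(species, size=n_named, replace=False)
    ) if n_named else set()
    lineage_info = {
        sp: LineageInfo(
            nominal_name=f"Nominalis {sp}" if sp in named else None,
            has_morph_data=True,
            has_acoustic_data=True,
        )
        for sp in species
    }
    ev = EvidenceTable(lineage_info=lineage_info)
    for i in range(len(species)):
        for j in range(i + 1, len(species)):
            ev.set_pair(
                species[i],
                species[j],
                PairEvidence(
                    morph_diff="yes" if rng.random() < p_morph else "no",
                    acoustic_diff="yes" if rng.random() < p_acoust else "no",
                    reference_split="unknown",
                ),
            )
    return ev


@dataclass
class SyntheticDataset:
    """All artifacts of one simulated study, mutually consistent."""

    config: SimConfig
    species_tree: UltrametricTree
    gene_tree: UltrametricTree
    alignment: Alignment
    species_map: dict[str, str]  # sequence id -> true species
    evidence: EvidenceTable

    def true_partition_groups(self) -> list[list[str]]:
        groups: dict[str, list[str]] = {}
        for sid, sp in self.species_map.items():
            groups.setdefault(sp, []).append(sid)
        return [sorted(g) for _, g in sorted(groups.items())]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "species_tree": out / "species_tree.nwk",
            "gene_tree": out / "gene_tree.nwk",
            "alignment": out / "alignment.fasta",
            "evidence": out / "evidence.csv",
            "lineages": out / "lineages.csv",
            "id_map": out / "id_map.csv",
            "truth": out / "truth.json",
        }
        self.species_tree.write_newick(paths["species_tree"])
        self.gene_tree.write_newick(paths["gene_tree"])
        write_fasta(self.alignment, paths["alignment"])
        self.evidence.to_csvs(paths["evidence"], paths["lineages"])
        with open(paths["id_map"], "w") as fh:
            fh.write("id,lineage\n")
            for sid, sp in sorted(self.species_map.items()):
                fh.write(f"{sid},{sp}\n")
        truth = {
            "config": asdict(self.config),
            "species_map": dict(sorted(self.species_map.items())),
        }
        paths["truth"].write_text(json.dumps(truth, indent=2) + "\n")
        return paths


def make_dataset(cfg: SimConfig) -> SyntheticDataset:
    """Chain the four simulators under one seed into a full dataset."""
    ss = np.random.SeedSequence(cfg.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(4)]
    species_tree = sim_yule_tree(cfg.n_species, cfg.speciation_rate, rngs[0])
    if cfg.min_species_divergence is not None and cfg.n_species >= 2:
        youngest = min(species_tree.internal_heights())
        if youngest > 0:
            species_tree.rescale(cfg.min_species_divergence / youngest)
    if cfg.n_species >= 2 or cfg.samples_per_species >= 2:
        gene_tree, species_map = sim_msc_gene_tree(
            species_tree, cfg.samples_per_species, cfg.theta, rngs[1]
        )
    else:
        tip = species_tree.tips()[0]
        gene_tree = UltrametricTree(TreeNode(name=f"{tip.name}_1", height=0.0))
        species_map = {f"{tip.name}_1": tip.name}
    alignment = sim_k2p_sequences(
        gene_tree, cfg.seq_length, cfg.subst_rate, cfg.kappa, rngs[2]
    )
    evidence = sim_evidence_table(
        [t.name for t in species_tree.tips()],
        cfg.p_morph,
        cfg.p_acoust,
        cfg.frac_named,
        rngs[3],
    )
    return SyntheticDataset(
        config=cfg,
        species_tree=species_tree,
        gene_tree=gene_tree,
        alignment=alignment,
        species_map=species_map,
        evidence=evidence,
    )
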