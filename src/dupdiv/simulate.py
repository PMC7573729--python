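"""Synthetic gene-family generator.

Emulates the statistical structure the divergence analysis assumes, so every
pipeline stage can be exercised without any external data:

* a duplication-generated family tree (Yule pure-birth process; waiting times
  exponential in the number of extant lineages, with a final exponential
  stretch so terminal branches are never zero);
* codon sequences evolved along the tree by a Gillespie single-nucleotide
  process (HKY-style proposal rates with transition/transversion ratio
  kappa), where proposals creating stop codons are rejected and
  nonsynonymous proposals are accepted with per-branch probability omega --
  so omega is exactly the realized dN/dS acceptance ratio;
* tissue expression profiles evolved on the log scale under one of three
  regimes:

  - ``gradual_bm``: Brownian drift with rate sigma2 along every branch, so
    expression divergence grows with patristic distance (the gradual-change
    null that sub-functionalization tests reject or not);
  - ``rapid_partition``: nested complementary domain partitioning.  Each
    duplication node splits the parent's retained-tissue set into two random
    complementary halves, one per daughter, so every pair of extant genes
    ends up expressed in disjoint tissue subsets -- divergence saturates at
    the first duplication separating two genes and is essentially
    independent of branch lengths.  A tip profile is ``jump`` in its
    retained tissues plus tissue-level noise (``tip_noise``) and only small
    Brownian drift;
  - ``neo_burst``: drift everywhere plus partition-style jumps confined to
    designated burst branches (the same branches can carry elevated omega),
    emulating neo-functionalization.

Everything is bit-reproducible from (config, seeds).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .alignment import CodonAlignment, translate, write_fasta
from .errors import DupdivError
from .kaks import STOP_CODONS
from .models import SubstitutionModel
from .trees import to_newick, write_newick

_NUC = "ACGT"

REGIMES = ("gradual_bm", "rapid_partition", "neo_burst")


@dataclass(frozen=True)
class SimulationConfig:
    """Full recipe for one synthetic gene family."""

    n_tips: int = 8
    birth_rate: float = 2.0
    n_codons: int = 300
    kappa: float = 2.0
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    omega: float = 0.2
    omega_burst: float = 1.0
    burst_branches: tuple[str, ...] = ()
    n_tissues: int = 12
    regime: str = "gradual_bm"
    sigma2: float = 1.0
    jump: float = 3.0
    drift_sigma2: float = 0.01
    tip_noise: float = 2.0
    gene_prefix: str = ""
    seed_tree: int = 1
    seed_sequence: int = 2
    seed_expression: int = 3

    def __post_init__(self):
        if self.n_tips < 3 or self.n_tissues < 3:
            raise DupdivError("need n_tips >= 3 and n_tissues >= 3")
        if self.birth_rate <= 0 or self.kappa <= 0:
            raise DupdivError("rates must be > 0")
        if self.omega < 0 or self.omega > 1 or self.omega_burst < 0 or self.omega_burst > 1:
            raise DupdivError("omega acceptance probabilities must lie in [0, 1]")
        if self.n_codons < 50:
            raise DupdivError("root sequence must be >= 50 codons")
        if self.regime not in REGIMES:
            raise DupdivError(f"unknown regime {self.regime!r}; one of {REGIMES}")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        d = json.loads(text)
        for key in ("base_freqs", "burst_branches"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SimulationTruth:
    config: SimulationConfig
    newick: str
    branch_omega: dict[str, float]
    expected_mantel_sign: str  # "positive" | "none"

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": asdict(self.config),
                "newick": self.newick,
                "branch_omega": self.branch_omega,
                "expected_mantel_sign": self.expected_mantel_sign,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SimulationTruth":
        d = json.loads(text)
        cfg = d.pop("config")
        for key in ("base_freqs", "burst_branches"):
            cfg[key] = tuple(cfg[key])
        return cls(config=SimulationConfig(**cfg), **d)


# ----------------------------------------------------------------------
# Tree
# ----------------------------------------------------------------------

def simulate_family_tree(
    n_tips: int, birth_rate: float, seed: int, label_prefix: str = ""
) -> dendropy.Tree:
    """Yule pure-birth tree with ``n_tips`` tips.

    Branch lengths are exponential waiting times with total rate
    (number of lineages) * birth_rate; after the last duplication all tips
    are extended by one further Exp(n * birth_rate) stretch.  Tips are
    labeled g1..gn in order of creation; internal nodes are labeled in
    preorder root, n1, n2, ... so per-branch maps can be keyed by the child
    node's label.
    """
    if n_tips < 3 or birth_rate <= 0:
        raise DupdivError("need n_tips >= 3 and birth_rate > 0")
    rng = np.random.default_rng(seed)
    taxon_ns = dendropy.TaxonNamespace()
    root = dendropy.Node()
    first = [dendropy.Node(), dendropy.Node()]
    for child in first:
        root.add_child(child)
        child.edge.length = 0.0
    active = list(first)
    while len(active) < n_tips:
        wait = rng.exponential(1.0 / (len(active) * birth_rate))
        for node in active:
            node.edge.length += wait
        split = active[rng.integers(len(active))]
        kids = [dendropy.Node(), dendropy.Node()]
        for child in kids:
            split.add_child(child)
            child.edge.length = 0.0
        active.remove(split)
        active.extend(kids)
    wait = rng.exponential(1.0 / (len(active) * birth_rate))
    for node in active:
        node.edge.length += wait

    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.seed_node = root
    tip_counter = internal_counter = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            tip_counter += 1
            node.taxon = taxon_ns.new_taxon(f"{label_prefix}g{tip_counter}")
        elif node.parent_node is None:
            node.label = "root"
        else:
            internal_counter += 1
            node.label = f"n{internal_counter}"
    return tree


def branch_labels(tree: dendropy.Tree) -> list[str]:
    """Child-node labels identifying every branch of the tree."""
    out = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        out.append(node.taxon.label if node.is_leaf() else node.label)
    return out


def resolve_omega_map(tree: dendropy.Tree, config: SimulationConfig) -> dict[str, float]:
    omegas = {}
    burst = set(config.burst_branches)
    for label in branch_labels(tree):
        omegas[label] = config.omega_burst if label in burst else config.omega
    missing = burst - set(omegas)
    if missing:
        raise DupdivError(f"burst branches not in tree: {sorted(missing)}")
    return omegas


# ----------------------------------------------------------------------
# Codon sequences
# ----------------------------------------------------------------------

def _codon_str(seq: np.ndarray, codon_idx: int) -> str:
    i = 3 * codon_idx
    return "".join(_NUC[k] for k in seq[i : i + 3])


def _root_sequence(n_codons: int, pi: np.ndarray, rng) -> np.ndarray:
    seq = np.empty(3 * n_codons, dtype=np.int64)
    for k in range(n_codons):
        while True:
            cod = rng.choice(4, size=3, p=pi)
            if "".join(_NUC[c] for c in cod) not in STOP_CODONS:
                seq[3 * k : 3 * k + 3] = cod
                break
    return seq


def _translate_codon(codon: str) -> str:
    from .kaks import _AA

    return _AA[codon]


def _evolve_branch(seq, t, q, omega, rng):
    """Gillespie simulation of one branch; returns the evolved copy."""
    seq = seq.copy()
    exit_rate = -q[seq, seq]  # per-site rate of proposing any change
    total = exit_rate.sum()
    clock = rng.exponential(1.0 / total)
    while clock <= t:
        site = rng.choice(len(seq), p=exit_rate / total)
        x = seq[site]
        rates = q[x].copy()
        rates[x] = 0.0
        y = rng.choice(4, p=rates / rates.sum())
        codon_idx = site // 3
        old_codon = _codon_str(seq, codon_idx)
        new = list(old_codon)
        new[site % 3] = _NUC[y]
        new_codon = "".join(new)
        accept = False
        if new_codon not in STOP_CODONS:
            if _translate_codon(new_codon) == _translate_codon(old_codon):
                accept = True
            else:
                accept = rng.random() < omega
        if accept:
            seq[site] = y
            exit_rate[site] = -q[y, y]
            total = exit_rate.sum()
        clock += rng.exponential(1.0 / total)
    return seq


def simulate_codon_sequences(
    tree: dendropy.Tree,
    n_codons: int,
    kappa: float,
    base_freqs,
    omega_map: dict[str, float],
    seed: int,
) -> CodonAlignment:
    """Evolve codon sequences down the tree; see module docstring.

    Branch lengths are in expected proposal events per nucleotide site (the
    HKY proposal process is normalized to rate 1 at equilibrium); the
    realized substitution rate is lower on branches with omega < 1.
    """
    if n_codons < 50:
        raise DupdivError("root sequence must be >= 50 codons")
    labels = set(branch_labels(tree))
    missing = labels - set(omega_map)
    if missing:
        raise DupdivError(f"omega_map missing branches: {sorted(missing)}")
    pi = np.asarray(base_freqs, dtype=float)
    pi = pi / pi.sum()
    q = SubstitutionModel.hky(kappa, pi).Q
    rng = np.random.default_rng(seed)
    seqs: dict[int, np.ndarray] = {}
    tip_rows: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            seqs[id(node)] = _root_sequence(n_codons, pi, rng)
            continue
        label = node.taxon.label if node.is_leaf() else node.label
        parent_seq = seqs[id(node.parent_node)]
        child_seq = _evolve_branch(
            parent_seq, node.edge.length, q, omega_map[label], rng
        )
        seqs[id(node)] = child_seq
        if node.is_leaf():
            tip_rows[label] = "".join(_NUC[k] for k in child_seq)
    ids = tuple(sorted(tip_rows))
    return CodonAlignment(ids, tuple(tip_rows[i] for i in ids))


# ----------------------------------------------------------------------
# Expression
# ----------------------------------------------------------------------

def simulate_expression(
    tree: dendropy.Tree,
    n_tissues: int,
    regime: str,
    params: dict | None = None,
    seed: int = 0,
    log_scale: bool = False,
) -> pd.DataFrame:
    """Tissue expression profiles for every tip, one row per gene.

    Profiles evolve on the log scale (see module docstring for the regimes)
    and are exponentiated unless ``log_scale`` is True.
    """
    if regime not in REGIMES:
        raise DupdivError(f"unknown regime {regime!r}")
    p = dict(params or {})
    sigma2 = float(p.get("sigma2", 1.0))
    jump = float(p.get("jump", 3.0))
    drift_sigma2 = float(p.get("drift_sigma2", 0.01))
    tip_noise = float(p.get("tip_noise", 2.0))
    burst = set(p.get("burst_branches", ()))
    rng = np.random.default_rng(seed)
    profiles: dict[int, np.ndarray] = {}
    partitions: dict[int, list] = {}
    retained: dict[int, list] = {}
    rows: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            profiles[id(node)] = np.zeros(n_tissues)
            retained[id(node)] = list(range(n_tissues))
        else:
            label = node.taxon.label if node.is_leaf() else node.label
            parent = profiles[id(node.parent_node)]
            t = node.edge.length
            if regime == "gradual_bm":
                val = parent + rng.normal(0.0, np.sqrt(sigma2 * t), n_tissues)
            elif regime == "rapid_partition":
                # the parent's retained-tissue set is split into complementary
                # halves when its first child is visited; the first child takes
                # one half, the second the other
                pid = id(node.parent_node)
                if pid not in partitions:
                    parent_set = retained[pid]
                    perm = rng.permutation(len(parent_set))
                    half = len(parent_set) // 2
                    partitions[pid] = [
                        [parent_set[i] for i in perm[:half]],
                        [parent_set[i] for i in perm[half:]],
                    ]
                    mine = partitions[pid][0]
                else:
                    mine = partitions[pid][1]
                retained[id(node)] = mine
                val = parent + rng.normal(
                    0.0, np.sqrt(drift_sigma2 * t), n_tissues
                )
                if node.is_leaf():
                    domain = np.zeros(n_tissues)
                    domain[mine] = jump
                    val = val + domain + rng.normal(0.0, tip_noise, n_tissues)
            else:  # neo_burst
                val = parent + rng.normal(0.0, np.sqrt(drift_sigma2 * t), n_tissues)
                if label in burst:
                    perm = rng.permutation(n_tissues)
                    sign = np.full(n_tissues, -1.0)
                    sign[perm[: n_tissues // 2]] = 1.0
                    val = val + jump * sign
            profiles[id(node)] = val
            if node.is_leaf():
                rows[label] = val
    ids = sorted(rows)
    data = np.vstack([rows[i] for i in ids])
    if not log_scale:
        data = np.exp(data)
    return pd.DataFrame(
        data, index=ids, columns=[f"tissue{k+1}" for k in range(n_tissues)]
    )


# ----------------------------------------------------------------------
# Dataset assembly
# ----------------------------------------------------------------------

def generate_dataset(config: SimulationConfig, out_dir) -> SimulationTruth:
    """Simulate one family and write codon FASTA, protein FASTA, expression
    TSV, the true tree (Newick) and the truth JSON into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree = simulate_family_tree(
        config.n_tips, config.birth_rate, config.seed_tree, config.gene_prefix
    )
    omega_map = resolve_omega_map(tree, config)
    aln = simulate_codon_sequences(
        tree,
        config.n_codons,
        config.kappa,
        config.base_freqs,
        omega_map,
        config.seed_sequence,
    )
    expr = simulate_expression(
        tree,
        config.n_tissues,
        config.regime,
        {
            "sigma2": config.sigma2,
            "jump": config.jump,
            "drift_sigma2": config.drift_sigma2,
            "tip_noise": config.tip_noise,
            "burst_branches": config.burst_branches,
        },
        config.seed_expression,
    )
    truth = SimulationTruth(
        config=config,
        newick=to_newick(tree),
        branch_omega=omega_map,
        expected_mantel_sign="positive" if config.regime == "gradual_bm" else "none",
    )
    write_fasta(aln, out / "codon.fasta")
    write_fasta(translate(aln), out / "protein.fasta")
    expr.to_csv(out / "expression.tsv", sep="\t", float_format="%.17g")
    write_newick(tree, out / "tree.nwk")
    (out / "truth.json").write_text(truth.to_json() + "\n", encoding="utf-8")
    return truth


FIXTURE_REGIMES = ("gradual_bm", "rapid_partition", "neo_burst")


def fixture_configs(seed: int = 20240101) -> dict[str, SimulationConfig]:
    """Three small gene classes, one per expression regime.

    8 genes, 300 codons and 12 tissues per class: large enough for every
    pipeline stage to produce a defined result, small enough to regenerate
    in well under a second.
    """
    configs = {}
    for k, regime in enumerate(FIXTURE_REGIMES):
        name = f"fam{k + 1}"
        configs[name] = SimulationConfig(
            regime=regime,
            gene_prefix=f"{name}_",
            burst_branches=("n1",) if regime == "neo_burst" else (),
            seed_tree=seed % 2**31 + 10 * k,
            seed_sequence=seed % 2**31 + 10 * k + 1,
            seed_expression=seed % 2**31 + 10 * k + 2,
        )
    return configs


def generate_multiclass_fixture(out_dir, seed: int = 20240101) -> Path:
    """Write the packaged-style 3-class dataset plus a pipeline config JSON.

    Returns the path of the written pipeline config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    exprs = []
    class_entries = []
    for name, cfg in fixture_configs(seed).items():
        generate_dataset(cfg, out / name)
        exprs.append(pd.read_csv(out / name / "expression.tsv", sep="\t", index_col=0))
        class_entries.append(
            {
                "name": name,
                "codon_fasta": f"{name}/codon.fasta",
                "protein_fasta": f"{name}/protein.fasta",
            }
        )
    pd.concat(exprs).to_csv(out / "expression.tsv", sep="\t", float_format="%.17g")
    pipeline_cfg = {
        "classes": class_entries,
        "expression_tsv": "expression.tsv",
        "model": "GTR+G+I",
        "alpha": 1.0,
        "p_inv": 0.0,
        "boot_n": 25,
        "perms": 999,
        "seed": 1,
    }
    cfg_path = out / "pipeline_config.json"
    cfg_path.write_text(
        json.dumps(pipeline_cfg, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return cfg_path
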