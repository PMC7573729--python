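"""End-to-end orchestration: config validation, per-class analysis, reports.

For each gene class the pipeline computes

1. expression: per-gene scaling, then pairwise 1 - Pearson r distances;
2. genetics: ML pairwise distances under the configured model, an NJ tree
   with bootstrap supports, and the cophenetic distances from that tree
   (the default genetic distance; raw pairwise ML distances by flag);
3. selection: the NG86 pairwise omega table with the 0 < omega < 9 validity
   filter;

then runs the within-class Mantel tests and between-class weighted
regressions.  A per-class failure is isolated and recorded; the run fails
only if every class fails.  Given identical config and inputs the numeric
outputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .alignment import read_fasta, translate
from .distmatrix import DistanceMatrix
from .errors import ConfigError
from .expression import (
    ScalingReport,
    correlation_distance,
    read_expression_tsv,
    scale_rows,
)
from .kaks import pairwise_kaks_table
from .mldist import bootstrap_support, distance_matrix
from .models import RateMixture, SubstitutionModel
from .stats import run_divergence_suite
from .trees import cophenetic, to_newick

MODEL_NAMES = ("JTT+G+I", "GTR+G+I", "JC69")


@dataclass
class ClassSpec:
    name: str
    codon_fasta: str
    protein_fasta: str | None = None


@dataclass
class PipelineConfig:
    classes: list[ClassSpec]
    expression_tsv: str
    model: str = "GTR+G+I"
    alpha: float = 1.0
    p_inv: float = 0.0
    gamma_categories: int = 4
    boot_n: int = 100
    perms: int = 999
    seed: int = 1
    tail: str = "upper"
    genetic_distance: str = "cophenetic"  # or "pairwise"
    base_dir: Path = field(default_factory=Path)

    def path(self, p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else self.base_dir / q


def validate_config(path) -> PipelineConfig:
    """Parse and validate a pipeline config JSON; collect *all* violations."""
    path = Path(path)
    violations: list[str] = []
    try:
        raw = json.loads(path.read_text(encoding="utf-8"))
    except (OSError, json.JSONDecodeError) as exc:
        raise ConfigError([f"config: cannot read JSON ({exc})"]) from exc

    known = {
        "classes", "expression_tsv", "model", "alpha", "p_inv",
        "gamma_categories", "boot_n", "perms", "seed", "tail",
        "genetic_distance",
    }
    for key in raw:
        if key not in known:
            violations.append(f"config.{key}: unknown key")

    classes = []
    for i, entry in enumerate(raw.get("classes", []) or []):
        prefix = f"classes[{i}]"
        if not isinstance(entry, dict):
            violations.append(f"{prefix}: must be an object")
            continue
        name = entry.get("name")
        if not name:
            violations.append(f"{prefix}.name: required")
        fasta = entry.get("codon_fasta")
        if not fasta:
            violations.append(f"{prefix}.codon_fasta: required")
        elif not (path.parent / fasta).exists() and not Path(fasta).exists():
            violations.append(f"{prefix}.codon_fasta: file not found: {fasta}")
        prot = entry.get("protein_fasta")
        if prot and not (path.parent / prot).exists() and not Path(prot).exists():
            violations.append(f"{prefix}.protein_fasta: file not found: {prot}")
        classes.append(ClassSpec(name or f"class{i}", fasta or "", prot))
    if not classes:
        violations.append("classes: at least one gene class required")
    names = [c.name for c in classes]
    if len(names) != len(set(names)):
        violations.append("classes: duplicate class names")

    expr = raw.get("expression_tsv")
    if not expr:
        violations.append("expression_tsv: required")
    elif not (path.parent / expr).exists() and not Path(expr).exists():
        violations.append(f"expression_tsv: file not found: {expr}")

    model = raw.get("model", "GTR+G+I")
    if model not in MODEL_NAMES:
        violations.append(f"model: must be one of {MODEL_NAMES}, got {model!r}")
    tail = raw.get("tail", "upper")
    if tail not in ("upper", "two"):
        violations.append("tail: must be 'upper' or 'two'")
    gd = raw.get("genetic_distance", "cophenetic")
    if gd not in ("cophenetic", "pairwise"):
        violations.append("genetic_distance: must be 'cophenetic' or 'pairwise'")
    for key, typ in (("alpha", (int, float)), ("p_inv", (int, float)),
                     ("gamma_categories", int), ("boot_n", int),
                     ("perms", int), ("seed", int)):
        if key in raw and not isinstance(raw[key], typ):
            violations.append(f"{key}: expected {typ[0].__name__ if isinstance(typ, tuple) else typ.__name__}")

    cfg = PipelineConfig(
        classes=classes,
        expression_tsv=expr or "",
        model=model if model in MODEL_NAMES else "GTR+G+I",
        alpha=float(raw.get("alpha", 1.0)),
        p_inv=float(raw.get("p_inv", 0.0)),
        gamma_categories=int(raw.get("gamma_categories", 4)),
        boot_n=int(raw.get("boot_n", 100)),
        perms=int(raw.get("perms", 999)),
        seed=int(raw.get("seed", 1)),
        tail=tail if tail in ("upper", "two") else "upper",
        genetic_distance=gd,
        base_dir=path.parent,
    )

    # cross-reference: a gene id may belong to at most one class
    seen: dict[str, str] = {}
    for cls in classes:
        fasta_path = cfg.path(cls.codon_fasta)
        if not fasta_path.exists():
            continue
        try:
            aln = read_fasta(fasta_path, "codon")
        except Exception as exc:
            violations.append(f"classes[{cls.name}].codon_fasta: {exc}")
            continue
        for gid in aln.ids:
            if gid in seen and seen[gid] != cls.name:
                violations.append(
                    f"gene {gid!r} claimed by classes {seen[gid]!r} and {cls.name!r}"
                )
            seen[gid] = cls.name

    if violations:
        raise ConfigError(violations)
    return cfg


# ----------------------------------------------------------------------

def _build_model(cfg: PipelineConfig, aln):
    if cfg.model == "JC69":
        model = SubstitutionModel.jc69()
        mixture = RateMixture()
        return model, mixture, "nucleotide"
    if cfg.model == "GTR+G+I":
        import numpy as np

        counts = np.zeros(4)
        index = {c: i for i, c in enumerate("ACGT")}
        for row in aln.rows:
            for ch in row:
                if ch in index:
                    counts[index[ch]] += 1
        freqs = counts / counts.sum() if counts.sum() else None
        model = SubstitutionModel.gtr(freqs=freqs)
        mixture = RateMixture.discrete_gamma(cfg.alpha, cfg.gamma_categories, cfg.p_inv)
        return model, mixture, "nucleotide"
    model = SubstitutionModel.jtt()
    mixture = RateMixture.discrete_gamma(cfg.alpha, cfg.gamma_categories, cfg.p_inv)
    return model, mixture, "amino-acid"


@dataclass
class ClassArtifacts:
    name: str
    genetic: DistanceMatrix
    expression: DistanceMatrix
    omega: DistanceMatrix
    kaks_table: object
    tree_newick: str
    scaled_expression: object
    dropped_constant: list[str]
    n_genes: int


@dataclass
class RunReport:
    classes: dict[str, ClassArtifacts]
    failures: dict[str, str]
    divergence: object
    provenance: dict


def run_analysis(cfg: PipelineConfig) -> RunReport:
    expr_all = read_expression_tsv(cfg.path(cfg.expression_tsv))
    artifacts: dict[str, ClassArtifacts] = {}
    failures: dict[str, str] = {}
    for cls in cfg.classes:
        try:
            artifacts[cls.name] = _analyze_class(cfg, cls, expr_all)
        except Exception as exc:
            failures[cls.name] = f"{type(exc).__name__}: {exc}"
    if not artifacts:
        raise ConfigError(
            [f"{name}: {msg}" for name, msg in failures.items()]
            or ["no classes analyzed"]
        )
    suite_input = {
        name: {"genetic": a.genetic, "expression": a.expression, "omega": a.omega}
        for name, a in artifacts.items()
    }
    divergence = run_divergence_suite(
        suite_input, n_perm=cfg.perms, seed=cfg.seed, tail=cfg.tail
    )
    provenance = {
        "version": __version__,
        "model": cfg.model,
        "alpha": cfg.alpha,
        "p_inv": cfg.p_inv,
        "gamma_categories": cfg.gamma_categories,
        "boot_n": cfg.boot_n,
        "perms": cfg.perms,
        "seed": cfg.seed,
        "tail": cfg.tail,
        "genetic_distance": cfg.genetic_distance,
        "config_hash": _config_hash(cfg),
    }
    return RunReport(artifacts, failures, divergence, provenance)


def _analyze_class(cfg: PipelineConfig, cls: ClassSpec, expr_all) -> ClassArtifacts:
    codon_aln = read_fasta(cfg.path(cls.codon_fasta), "codon")
    genes = [g for g in codon_aln.ids if g in expr_all.index]
    scaling = ScalingReport()
    scaled = scale_rows(expr_all.loc[genes], scaling)
    expr_dm = correlation_distance(scaled)

    if cfg.model == "JTT+G+I":
        if cls.protein_fasta:
            aln = read_fasta(cfg.path(cls.protein_fasta), "amino-acid")
        else:
            aln = translate(codon_aln)
    else:
        aln = codon_aln
    model, mixture, _ = _build_model(cfg, aln)
    tree = bootstrap_support(
        aln, model, mixture, n_boot=cfg.boot_n, seed=cfg.seed
    )
    if cfg.genetic_distance == "cophenetic":
        genetic = cophenetic(tree)
    else:
        genetic = distance_matrix(aln, model, mixture)
    kaks_table, omega_dm = pairwise_kaks_table(codon_aln)

    common = sorted(set(expr_dm.labels) & set(genetic.labels))
    return ClassArtifacts(
        name=cls.name,
        genetic=genetic.reorder(common),
        expression=expr_dm.reorder(common),
        omega=omega_dm.reorder(common),
        kaks_table=kaks_table,
        tree_newick=to_newick(tree),
        scaled_expression=scaled,
        dropped_constant=scaling.dropped_constant,
        n_genes=len(common),
    )


def _config_hash(cfg: PipelineConfig) -> str:
    payload = json.dumps(
        dataclasses.asdict(cfg), default=str, sort_keys=True
    ).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


# ----------------------------------------------------------------------

def _result_to_dict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _result_to_dict(v) for k, v in dataclasses.asdict(obj).items()}
    return obj


def write_report(report: RunReport, out_dir) -> list[Path]:
    """Write per-class artifacts, the summary tables, a JSON report, a
    checksum manifest and a log; returns the list of files written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(relpath: str, writer):
        p = out / relpath
        p.parent.mkdir(parents=True, exist_ok=True)
        writer(p)
        written.append(p)

    for name, art in sorted(report.classes.items()):
        d = f"classes/{name}"
        emit(f"{d}/genetic.tsv", art.genetic.write_tsv)
        emit(f"{d}/expression.tsv", art.expression.write_tsv)
        emit(f"{d}/omega.tsv", art.omega.write_tsv)
        emit(
            f"{d}/kaks_table.tsv",
            lambda p, t=art.kaks_table: t.to_csv(p, sep="\t", index=False,
                                                 float_format="%.17g"),
        )
        emit(
            f"{d}/tree.nwk",
            lambda p, s=art.tree_newick: p.write_text(s + "\n", encoding="utf-8"),
        )
        emit(
            f"{d}/scaled_expression.tsv",
            lambda p, e=art.scaled_expression: e.to_csv(p, sep="\t",
                                                        float_format="%.17g"),
        )

    div = report.divergence
    mantel_rows = []
    for name, entry in sorted(div.within.items()):
        for test, res in entry.items():
            if test == "seed":
                continue
            row = {"class": name, "test": test}
            if isinstance(res, str):
                row["status"] = res
            else:
                row.update(_result_to_dict(res))
                row["status"] = "ok"
            mantel_rows.append(row)
    import pandas as pd

    emit(
        "within_class_tests.tsv",
        lambda p: pd.DataFrame(mantel_rows).to_csv(p, sep="\t", index=False,
                                                   float_format="%.17g"),
    )
    emit(
        "class_summary.tsv",
        lambda p: pd.DataFrame(
            [_result_to_dict(s) for s in div.summaries]
        ).to_csv(p, sep="\t", index=False, float_format="%.17g"),
    )
    between_rows = []
    for label, res in sorted(div.between.items()):
        row = {"test": label}
        if isinstance(res, str):
            row["status"] = res
        else:
            row.update(_result_to_dict(res))
            row["status"] = "ok"
        between_rows.append(row)
    emit(
        "between_class_regressions.tsv",
        lambda p: pd.DataFrame(between_rows).to_csv(p, sep="\t", index=False,
                                                    float_format="%.17g"),
    )

    summary = {
        "provenance": report.provenance,
        "failures": report.failures,
        "within": {
            name: {
                test: (_result_to_dict(res) if not isinstance(res, str) else res)
                for test, res in entry.items()
            }
            for name, entry in report.divergence.within.items()
        },
        "between": {
            label: (_result_to_dict(res) if not isinstance(res, str) else res)
            for label, res in report.divergence.between.items()
        },
        "summaries": [_result_to_dict(s) for s in report.divergence.summaries],
        "warnings": report.divergence.warnings,
        "seeds": report.divergence.seeds,
    }
    emit(
        "report.json",
        lambda p: p.write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        ),
    )

    manifest = {
        str(p.relative_to(out)): hashlib.sha256(p.read_bytes()).hexdigest()
        for p in written
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n",
                     encoding="utf-8")
    written.append(mpath)

    log = out / "run.log"
    lines = [
        f"timestamp: {time.strftime('%Y-%m-%dT%H:%M:%S')}",
        f"version: {report.provenance['version']}",
        f"config_hash: {report.provenance['config_hash']}",
        f"base_seed: {report.provenance['seed']}",
    ]
    for name, entry in sorted(report.divergence.within.items()):
        lines.append(f"class {name}: seed {entry.get('seed')}")
    for name, msg in sorted(report.failures.items()):
        lines.append(f"FAILED class {name}: {msg}")
    log.write_text("\n".join(lines) + "\n", encoding="utf-8")
    written.append(log)
    return written
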