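"""Seeded synthetic inputs with planted ground truth.

The generator emulates the kind of data the pipeline consumes in a real
study — two-group log2 expression matrices for miRNAs and mRNAs, a
scale-free miRNA-target catalog, and a STRING-style scored PPI catalog —
with known planted structure for end-to-end recovery tests:

* planted differential features (a log2 shift of ``delta`` in the case
  group, everything else exchangeable between groups);
* a planted dense PPI module whose members become topologically central
  (CORE) after the confidence filter;
* planted biomarker miRNAs whose out-degree sits far above the power-law
  background and whose targets concentrate in the dense module, so the
  two-step screen should nominate exactly them.

All randomness flows through one seeded ``numpy`` generator; the same
seed and configuration reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .network import InteractionCatalog, PPICatalog

__all__ = ["SyntheticConfig", "SyntheticTruth", "gen_expression", "gen_catalogs", "gen_bundle"]


@dataclass
class SyntheticConfig:
    """Generator settings; the defaults are the frozen design point.

    Sizes mirror the scale of the condition-specific networks this
    pipeline produces (tens of miRNAs, hundreds of genes) while keeping
    universes large enough that differential selection is a real filter.
    """

    # expression
    n_mirna_features: int = 300
    n_mrna_features: int = 2000
    n_case: int = 6
    n_control: int = 6
    n_de_mirnas: int = 31
    n_de_genes: int = 300
    delta: float = 2.0       # planted log2 shift
    sigma: float = 0.5       # per-sample noise SD, log2 units
    baseline_mean: float = 8.0
    case_label: str = "KTR"
    control_label: str = "Normal"
    # catalogs
    n_biomarkers: int = 3
    module_size: int = 12
    degree_exponent: float = -1.3
    min_out_degree: int = 10
    max_out_degree: int = 60
    biomarker_out_degree: int = 250
    ppi_attach_edges: int = 3      # edges each peripheral gene adds
    ppi_attach_power: float = 3.0  # preferential-attachment weight exponent
    ppi_background_p: float = 0.001  # extra uniform-random edge density
    module_density: float = 0.8
    module_score_low: float = 0.7  # module edges are high-confidence
    score_low: float = 0.4
    score_high: float = 1.0


@dataclass
class SyntheticTruth:
    """Planted structure, for recovery checks."""

    de_mirnas: dict[str, float]  # id -> signed log2 effect
    de_genes: dict[str, float]
    biomarkers: list[str]
    module_genes: list[str]
    config: SyntheticConfig
    seed: int

    def to_json(self, path) -> None:
        payload = {
            "de_mirnas": self.de_mirnas,
            "de_genes": self.de_genes,
            "biomarkers": self.biomarkers,
            "module_genes": self.module_genes,
            "config": dataclasses.asdict(self.config),
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            de_mirnas=payload["de_mirnas"],
            de_genes=payload["de_genes"],
            biomarkers=payload["biomarkers"],
            module_genes=payload["module_genes"],
            config=SyntheticConfig(**payload["config"]),
            seed=payload["seed"],
        )


def _mirna_ids(n: int) -> list[str]:
    return [f"miR-{i + 1}-5p" for i in range(n)]


def _gene_ids(n: int) -> list[str]:
    return [f"GENE{i + 1:04d}" for i in range(n)]


def _plant_expression(
    rng: np.random.Generator,
    feature_ids: list[str],
    planted: dict[str, float],
    n_case: int,
    n_control: int,
    sigma: float,
    baseline_mean: float,
    case_label: str,
    control_label: str,
    sample_prefix: str,
) -> ExpressionMatrix:
    n_samples = n_case + n_control
    baselines = rng.normal(baseline_mean, 1.5, size=len(feature_ids))
    values = baselines[:, None] + rng.normal(0.0, sigma, size=(len(feature_ids), n_samples))
    for i, fid in enumerate(feature_ids):
        if fid in planted:
            values[i, :n_case] += planted[fid]
    sample_ids = [f"{sample_prefix}_case{j + 1}" for j in range(n_case)] + [
        f"{sample_prefix}_ctrl{j + 1}" for j in range(n_control)
    ]
    group_of = {s: (case_label if j < n_case else control_label) for j, s in enumerate(sample_ids)}
    return ExpressionMatrix(feature_ids, sample_ids, values, group_of)


def gen_expression(
    config: SyntheticConfig, seed: int, which: str = "mirna"
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """One two-group expression matrix with planted differential features.

    ``which`` selects the miRNA- or mRNA-sized matrix.  Background
    features are i.i.d. Normal around a per-feature baseline in both
    groups; planted features get a +/-delta shift in the case group
    (signs alternate at random).
    """
    if config.n_case < 2 or config.n_control < 2:
        raise ValueError("need >= 2 samples per group")
    truth = _make_truth(config, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1 if which == "mirna" else 2]))
    if which == "mirna":
        ids, planted = _mirna_ids(config.n_mirna_features), truth.de_mirnas
    elif which == "mrna":
        ids, planted = _gene_ids(config.n_mrna_features), truth.de_genes
    else:
        raise ValueError("which must be 'mirna' or 'mrna'")
    matrix = _plant_expression(
        rng, ids, planted, config.n_case, config.n_control, config.sigma,
        config.baseline_mean, config.case_label, config.control_label, which,
    )
    return matrix, truth


def _make_truth(config: SyntheticConfig, seed: int) -> SyntheticTruth:
    if config.n_de_mirnas > config.n_mirna_features or config.n_de_genes > config.n_mrna_features:
        raise ValueError("planted set larger than feature universe")
    if config.module_size > config.n_de_genes or config.n_biomarkers > config.n_de_mirnas:
        raise ValueError("planted module/biomarkers larger than planted DE sets")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    mirnas = _mirna_ids(config.n_mirna_features)
    genes = _gene_ids(config.n_mrna_features)
    de_mirnas = sorted(rng.choice(len(mirnas), size=config.n_de_mirnas, replace=False))
    de_genes = sorted(rng.choice(len(genes), size=config.n_de_genes, replace=False))
    mir_effects = {
        mirnas[i]: float(config.delta * (1 if rng.random() < 0.5 else -1)) for i in de_mirnas
    }
    gene_effects = {
        genes[i]: float(config.delta * (1 if rng.random() < 0.5 else -1)) for i in de_genes
    }
    biomarkers = sorted(
        rng.choice(sorted(mir_effects), size=config.n_biomarkers, replace=False).tolist()
    )
    module_genes = sorted(
        rng.choice(sorted(gene_effects), size=config.module_size, replace=False).tolist()
    )
    return SyntheticTruth(mir_effects, gene_effects, biomarkers, module_genes, config, seed)


def _power_law_degrees(
    rng: np.random.Generator, n: int, exponent: float, k_min: int, k_max: int
) -> np.ndarray:
    ks = np.arange(k_min, k_max + 1, dtype=float)
    pmf = ks ** exponent
    pmf /= pmf.sum()
    return rng.choice(np.arange(k_min, k_max + 1), size=n, p=pmf)


def gen_catalogs(
    config: SyntheticConfig, seed: int
) -> tuple[InteractionCatalog, PPICatalog, SyntheticTruth]:
    """miRNA-target and PPI catalogs with planted biomarker structure.

    Background miRNA out-degrees follow a discrete power law (so miRNAs
    with many targets are few); planted biomarkers get a fixed high
    out-degree with the whole dense module among their targets.  The PPI
    catalog is Erdos-Renyi background plus the dense planted module, with
    combined scores Uniform(score_low, score_high) so the confidence
    filter removes a real fraction of edges.
    """
    truth = _make_truth(config, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    mirnas = _mirna_ids(config.n_mirna_features)
    genes = _gene_ids(config.n_mrna_features)

    pairs: set[tuple[str, str]] = set()
    degrees = _power_law_degrees(
        rng, len(mirnas), config.degree_exponent, config.min_out_degree, config.max_out_degree
    )
    biomarker_set = set(truth.biomarkers)
    module_set = set(truth.module_genes)
    # The dense module is the planted biomarkers' regulatory program:
    # biomarkers target every module gene, background miRNAs target the
    # rest of the gene universe uniformly.
    non_module = np.array([g for g in genes if g not in module_set])
    for i, m in enumerate(mirnas):
        if m in biomarker_set:
            k = min(config.biomarker_out_degree, len(genes))
            targets = set(truth.module_genes)
            extra = rng.choice(len(non_module), size=k, replace=False)
            for g in non_module[extra]:
                if len(targets) >= k:
                    break
                targets.add(str(g))
        else:
            idx = rng.choice(len(non_module), size=int(degrees[i]), replace=False)
            targets = {str(g) for g in non_module[idx]}
        pairs.update((m, g) for g in targets)
    catalog = InteractionCatalog.from_pairs(sorted(pairs))

    # PPI: dense planted module at the centre, peripheral genes attached by
    # preferential attachment (few hub genes, most genes at the border),
    # plus a thin layer of uniform background edges.
    ppi = PPICatalog()
    module = truth.module_genes
    module_set = set(module)

    def score() -> float:
        return float(rng.uniform(config.score_low, config.score_high))

    degree = {g: 0 for g in genes}

    def wire(a: str, b: str) -> None:
        key = (a, b) if a <= b else (b, a)
        if a == b or key in ppi.scores:
            return
        ppi.add(a, b, score())
        degree[a] += 1
        degree[b] += 1

    for i in range(len(module)):
        for j in range(i + 1, len(module)):
            if rng.random() < config.module_density:
                key = (module[i], module[j]) if module[i] <= module[j] else (module[j], module[i])
                ppi.add(*key, float(rng.uniform(config.module_score_low, config.score_high)))
                degree[module[i]] += 1
                degree[module[j]] += 1
    # Condition genes join the module-centred core first, so the
    # condition-specific subnetwork is itself hub-centred and scale-free;
    # the rest of the universe attaches afterwards.
    de_periphery = [g for g in sorted(truth.de_genes) if g not in module_set]
    other = [g for g in genes if g not in module_set and g not in truth.de_genes]
    rng.shuffle(de_periphery)
    rng.shuffle(other)
    attached = list(module)
    for g in de_periphery + other:
        weights = np.array([degree[h] + 1.0 for h in attached]) ** config.ppi_attach_power
        weights /= weights.sum()
        m_edges = min(config.ppi_attach_edges, len(attached))
        for h in rng.choice(len(attached), size=m_edges, replace=False, p=weights):
            wire(g, attached[int(h)])
        attached.append(g)
    n_genes = len(genes)
    n_extra = rng.binomial(n_genes * (n_genes - 1) // 2, config.ppi_background_p)
    for _ in range(int(n_extra)):
        i, j = rng.integers(0, n_genes, size=2)
        wire(genes[int(i)], genes[int(j)])
    return catalog, ppi, truth


def gen_bundle(config: SyntheticConfig, seed: int, out_dir) -> SyntheticTruth:
    """Write a complete fixture set (expression, groups, catalogs, GMT,
    truth JSON) under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mirna_expr, truth = gen_expression(config, seed, which="mirna")
    mrna_expr, _ = gen_expression(config, seed, which="mrna")
    catalog, ppi, _ = gen_catalogs(config, seed)

    for name, mat in (("mirna", mirna_expr), ("mrna", mrna_expr)):
        mat.to_frame().to_csv(out / f"{name}_expr.tsv", sep="\t")
        pd.DataFrame(sorted(mat.group_of.items())).to_csv(
            out / f"{name}_groups.tsv", sep="\t", header=False, index=False
        )
    pd.DataFrame(sorted(catalog.edges)).to_csv(
        out / "targets.tsv", sep="\t", header=False, index=False
    )
    pd.DataFrame(
        [(a, b, f"{s:.4f}") for (a, b), s in sorted(ppi.scores.items())]
    ).to_csv(out / "ppi.tsv", sep="\t", header=False, index=False)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    genes = _gene_ids(config.n_mrna_features)
    with open(out / "genesets.gmt", "w") as fh:
        fh.write("PLANTED_MODULE\tsynthetic dense module\t" + "\t".join(truth.module_genes) + "\n")
        for t in range(3):
            members = rng.choice(genes, size=25, replace=False)
            fh.write(f"RANDOM_SET_{t + 1}\tsynthetic background set\t" + "\t".join(members) + "\n")
    truth.to_json(out / "truth.json")
    return truth
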