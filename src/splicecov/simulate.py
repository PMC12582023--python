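"""Count-level simulation of differential-splicing experiments with
condition and covariate effects, plus the evaluation metrics.

Each simulated gene is one bunch whose introns proxy the gene's transcript
isoforms. Differential expression (DE) halves or doubles all isoform means
of a gene in the affected group; differential splicing (DS) swaps the two
largest isoform means. Condition effects are keyed on the condition label,
covariate effects on the covariate level (e.g. biological sex), so an
imbalanced covariate assignment across conditions confounds the two — the
scenario the covariate-aware models exist to untangle.

Counts are generated hierarchically, mirroring how junction reads arise:
a negative-binomial gene total around the per-sample library size, split
across isoforms by a multinomial whose proportions vary between samples
(Dirichlet around the gene's isoform mix — biological PSI variability),
with a small per-intron dropout probability for technical zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import CONDITION, SampleSheet
from .junctions import Bunch, CountMatrix, Intron
from .dsr import BunchCounts


@dataclass
class SimConfig:
    """Simulation parameters; defaults follow the benchmark design.

    ``n_de``/``n_ds``/``n_deds`` genes are modified between conditions;
    ``n_cov_de``/``n_cov_ds``/``n_cov_deds`` additional genes are modified
    between covariate levels (disjoint from the condition genes). Remaining
    genes are unmodified. ``sample_design`` maps condition -> {covariate
    level: sample count}; ``None`` means 10 samples per condition x
    covariate cell.
    """

    n_genes: int = 2000
    conditions: tuple = ("control", "disease")
    covariate: str = "sex"
    covariate_levels: tuple = ("F", "M")
    n_de: int = 200
    n_ds: int = 200
    n_deds: int = 200
    n_cov_de: int = 100
    n_cov_ds: int = 100
    n_cov_deds: int = 100
    sample_design: dict | None = None
    mean_expression: float = 150.0  # log-normal median of per-gene total mean
    expression_sd: float = 0.7  # log-scale sd of gene expression
    dispersion: float = 10.0  # NB theta of the gene total
    psi_concentration: float = 60.0  # Dirichlet concentration of per-sample PSI
    zero_inflation: float = 0.0  # per-intron technical dropout (off: bulk-like zeros arise from sampling)
    libsize_sd: float = 0.2  # log-normal library-size factor sd
    min_isoforms: int = 2
    max_isoforms: int = 4
    seed: int = 0


def balanced_design(conditions, levels, per_cell: int = 10) -> dict:
    return {c: {lv: per_cell for lv in levels} for c in conditions}


def imbalanced_pairwise_design(n_major: int = 8, n_minor: int = 2) -> dict:
    """The imbalanced two-condition layout: (8M, 2F) control vs (8F, 2M) disease."""
    return {
        "control": {"M": n_major, "F": n_minor},
        "disease": {"M": n_minor, "F": n_major},
    }


@dataclass
class GeneTruth:
    gene_id: str
    de_condition: bool = False
    ds_condition: bool = False
    de_covariate: bool = False
    ds_covariate: bool = False
    # conditions in which the condition-keyed modification is active
    affected_conditions: tuple = ()


@dataclass
class TruthTable:
    genes: dict = field(default_factory=dict)  # gene_id -> GeneTruth

    def dsa_target(self) -> set:
        """Genes with any condition-keyed change (DE, DS or both)."""
        return {
            g for g, t in self.genes.items() if t.de_condition or t.ds_condition
        }

    def dsr_target(self) -> set:
        """Genes with a condition-keyed splicing-ratio change (DS or DE+DS)."""
        return {g for g, t in self.genes.items() if t.ds_condition}

    def covariate_genes(self) -> set:
        return {
            g for g, t in self.genes.items() if t.de_covariate or t.ds_covariate
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene_id": g,
                "de_condition": t.de_condition,
                "ds_condition": t.ds_condition,
                "de_covariate": t.de_covariate,
                "ds_covariate": t.ds_covariate,
                "affected_conditions": ",".join(t.affected_conditions),
            }
            for g, t in sorted(self.genes.items())
        ]
        return pd.DataFrame(rows)


@dataclass
class SimExperiment:
    matrix: CountMatrix
    bunch_counts: list  # list of BunchCounts, one per gene
    sheet: SampleSheet
    truth: TruthTable
    feature_gene: dict  # intron key -> gene_id
    bunch_gene: dict  # bunch id -> gene_id


def _swap_top_two(means: np.ndarray) -> np.ndarray:
    out = means.copy()
    order = np.argsort(out)[::-1]
    out[order[0]], out[order[1]] = out[order[1]], out[order[0]]
    return out


def simulate_gene(
    base_isoform_means: np.ndarray,
    condition_mod: dict,
    covariate_mod: dict,
    sheet: SampleSheet,
    covariate: str,
    rng: np.random.Generator,
    dispersion: float = 10.0,
    psi_concentration: float = 60.0,
    zero_inflation: float = 0.0,
    lib_factors: np.ndarray | None = None,
) -> np.ndarray:
    """Per-sample isoform (intron) counts for one gene.

    ``condition_mod`` maps a condition label to ``(de_factor, ds_swap)``;
    ``covariate_mod`` does the same keyed on the covariate level. A DE
    modification multiplies all isoform means by the factor (changing the
    gene total); a DS modification swaps the two largest isoform means
    (changing the mix, not the total). Per sample, a negative-binomial
    gene total is split multinomially with Dirichlet-jittered proportions,
    then thinned by the technical dropout. Returns an (N, n_isoforms)
    integer matrix.
    """
    base = np.asarray(base_isoform_means, dtype=float)
    if base.size < 2 and any(m[1] for m in list(condition_mod.values()) + list(covariate_mod.values())):
        raise ValueError("a DS modification needs at least 2 isoforms")
    n = len(sheet.sample_ids)
    if lib_factors is None:
        lib_factors = np.ones(n)
    cond = list(sheet.conditions)
    cov = list(sheet.table[covariate]) if covariate in sheet.table.columns else [None] * n
    out = np.zeros((n, base.size), dtype=np.int64)
    for i in range(n):
        mu = base.copy()
        de_f, ds_s = condition_mod.get(cond[i], (1.0, False))
        if ds_s:
            mu = _swap_top_two(mu)
        mu = mu * de_f
        de_f, ds_s = covariate_mod.get(cov[i], (1.0, False))
        if ds_s:
            mu = _swap_top_two(mu)
        mu = mu * de_f
        total_mean = mu.sum() * lib_factors[i]
        # gene total: gamma-Poisson mixture with shape theta
        lam = rng.gamma(dispersion, total_mean / dispersion)
        total = rng.poisson(lam)
        if total > 0:
            props = rng.dirichlet(psi_concentration * mu / mu.sum())
            y = rng.multinomial(total, props)
        else:
            y = np.zeros(base.size, dtype=np.int64)
        if zero_inflation > 0:
            y = np.where(rng.random(base.size) < zero_inflation, 0, y)
        out[i] = y
    return out


def _make_sheet(config: SimConfig) -> SampleSheet:
    design = config.sample_design or balanced_design(
        config.conditions, config.covariate_levels
    )
    rows = []
    i = 0
    for cond in config.conditions:
        for lv in config.covariate_levels:
            for _ in range(design.get(cond, {}).get(lv, 0)):
                rows.append({"sample_id": f"s{i:03d}", CONDITION: cond, config.covariate: lv})
                i += 1
    return SampleSheet(pd.DataFrame(rows))


def _assign_categories(rng, n_genes, counts: dict) -> dict:
    """Disjoint random gene-index sets per category; error on overflow."""
    total = sum(counts.values())
    if total > n_genes:
        raise ValueError(f"{total} modified genes requested but only {n_genes} genes")
    chosen = rng.choice(n_genes, size=total, replace=False)
    out, k = {}, 0
    for name, c in counts.items():
        out[name] = set(chosen[k : k + c].tolist())
        k += c
    return out


def _gene_bases(config: SimConfig, rng) -> list:
    bases = []
    for _ in range(config.n_genes):
        m = int(rng.integers(config.min_isoforms, config.max_isoforms + 1))
        total = rng.lognormal(np.log(config.mean_expression), config.expression_sd)
        # isoform expression is highly skewed in real transcriptomes: draw
        # per-isoform levels log-normally and normalize, sorted descending
        levels = np.sort(rng.lognormal(0.0, 1.0, size=m))[::-1]
        props = levels / levels.sum()
        bases.append(total * props)
    return bases


def _assemble(config: SimConfig, sheet, bases, gene_cond_mods, gene_cov_mods, truth, rng):
    n = len(sheet.sample_ids)
    lib = rng.lognormal(0.0, config.libsize_sd, size=n)
    features, rows = [], []
    bunch_counts, feature_gene, bunch_gene = [], {}, {}
    for g, base in enumerate(bases):
        gid = f"g{g:05d}"
        counts = simulate_gene(
            base, gene_cond_mods.get(g, {}), gene_cov_mods.get(g, {}),
            sheet, config.covariate, rng,
            dispersion=config.dispersion,
            psi_concentration=config.psi_concentration,
            zero_inflation=config.zero_inflation,
            lib_factors=lib,
        )
        chrom = f"chr{(g % 22) + 1}"
        start = 10_000 + 100_000 * (g // 22)
        introns = []
        for m in range(base.size):
            end = start + 500 + 400 * m  # all introns share the start site
            iv = Intron(chrom=chrom, start=start, end=end, strand="+")
            introns.append(iv)
            features.append(iv.key)
            rows.append(counts[:, m])
            feature_gene[iv.key] = gid
        bunch = Bunch(id=f"{chrom}:{start}-{introns[-1].end}", introns=introns,
                      anchor=str(start))
        bunch_counts.append(BunchCounts(bunch=bunch, matrix=counts))
        bunch_gene[bunch.id] = gid
    df = pd.DataFrame(
        np.vstack(rows), index=pd.Index(features, tupleize_cols=False),
        columns=sheet.sample_ids,
    )
    return SimExperiment(
        matrix=CountMatrix(df), bunch_counts=bunch_counts, sheet=sheet,
        truth=truth, feature_gene=feature_gene, bunch_gene=bunch_gene,
    )


def build_pairwise_experiment(config: SimConfig | None = None) -> SimExperiment:
    """Two-condition experiment with disjoint condition- and covariate-modified genes."""
    config = config or SimConfig()
    if len(config.conditions) != 2:
        raise ValueError("pairwise experiment needs exactly 2 conditions")
    rng = np.random.default_rng(config.seed)
    sheet = _make_sheet(config)
    bases = _gene_bases(config, rng)
    cats = _assign_categories(rng, config.n_genes, {
        "de": config.n_de, "ds": config.n_ds, "deds": config.n_deds,
        "cov_de": config.n_cov_de, "cov_ds": config.n_cov_ds,
        "cov_deds": config.n_cov_deds,
    })
    affected_cond = config.conditions[1]
    affected_cov = config.covariate_levels[0]
    truth = TruthTable()
    gene_cond_mods, gene_cov_mods = {}, {}
    for g in range(config.n_genes):
        gid = f"g{g:05d}"
        t = GeneTruth(gene_id=gid)
        de = g in cats["de"] or g in cats["deds"]
        ds = g in cats["ds"] or g in cats["deds"]
        if de or ds:
            factor = 2.0 if (de and rng.random() < 0.5) else (0.5 if de else 1.0)
            gene_cond_mods[g] = {affected_cond: (factor, ds)}
            t.de_condition, t.ds_condition = de, ds
            t.affected_conditions = (affected_cond,)
        cde = g in cats["cov_de"] or g in cats["cov_deds"]
        cds = g in cats["cov_ds"] or g in cats["cov_deds"]
        if cde or cds:
            factor = 2.0 if (cde and rng.random() < 0.5) else (0.5 if cde else 1.0)
            gene_cov_mods[g] = {affected_cov: (factor, cds)}
            t.de_covariate, t.ds_covariate = cde, cds
        truth.genes[gid] = t
    return _assemble(config, sheet, bases, gene_cond_mods, gene_cov_mods, truth, rng)


def build_threeway_experiment(config: SimConfig | None = None) -> SimExperiment:
    """Three-condition experiment (control / disease / stage2).

    Per category, half of the condition-modified genes keep the disease
    change in stage2 and half revert to control in stage2; an equal number
    of additional genes change only in stage2. With the default counts the
    ratio target (DS plus DE+DS genes changed between any pair) has 800
    genes and the abundance target 1200.
    """
    config = config or SimConfig(conditions=("control", "disease", "stage2"))
    if len(config.conditions) != 3:
        raise ValueError("three-way experiment needs exactly 3 conditions")
    rng = np.random.default_rng(config.seed)
    sheet = _make_sheet(config)
    bases = _gene_bases(config, rng)
    cats = _assign_categories(rng, config.n_genes, {
        "de": config.n_de, "ds": config.n_ds, "deds": config.n_deds,
        "de2": config.n_de, "ds2": config.n_ds, "deds2": config.n_deds,
        "cov_de": config.n_cov_de, "cov_ds": config.n_cov_ds,
        "cov_deds": config.n_cov_deds,
    })
    disease, stage2 = config.conditions[1], config.conditions[2]
    affected_cov = config.covariate_levels[0]
    truth = TruthTable()
    gene_cond_mods, gene_cov_mods = {}, {}
    for g in range(config.n_genes):
        gid = f"g{g:05d}"
        t = GeneTruth(gene_id=gid)
        for grp, new in (("de", False), ("ds", False), ("deds", False),
                         ("de2", True), ("ds2", True), ("deds2", True)):
            if g not in cats[grp]:
                continue
            de = grp in ("de", "deds", "de2", "deds2")
            ds = grp in ("ds", "deds", "ds2", "deds2")
            factor = 2.0 if (de and rng.random() < 0.5) else (0.5 if de else 1.0)
            if new:
                # changed only in stage2 (disease vs stage2 difference)
                gene_cond_mods[g] = {stage2: (factor, ds)}
                t.affected_conditions = (stage2,)
            else:
                # changed in disease; half also keep the change in stage2
                if rng.random() < 0.5:
                    gene_cond_mods[g] = {disease: (factor, ds), stage2: (factor, ds)}
                    t.affected_conditions = (disease, stage2)
                else:
                    gene_cond_mods[g] = {disease: (factor, ds)}
                    t.affected_conditions = (disease,)
            t.de_condition, t.ds_condition = de, ds
        cde = g in cats["cov_de"] or g in cats["cov_deds"]
        cds = g in cats["cov_ds"] or g in cats["cov_deds"]
        if cde or cds:
            factor = 2.0 if (cde and rng.random() < 0.5) else (0.5 if cde else 1.0)
            gene_cov_mods[g] = {affected_cov: (factor, cds)}
            t.de_covariate, t.ds_covariate = cde, cds
        truth.genes[gid] = t
    return _assemble(config, sheet, bases, gene_cond_mods, gene_cov_mods, truth, rng)


# ---------------------------------------------------------------------------
# evaluation

@dataclass
class Metrics:
    sn: float
    pr: float
    f: float
    tp: int
    fp: int
    fn: int
    fp_covariate: int
    fp_extrinsic: int
    undefined_precision: bool = False

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sn, "precision": self.pr, "f_value": self.f,
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "fp_covariate": self.fp_covariate, "fp_extrinsic": self.fp_extrinsic,
        }


def f_value(sn: float, pr: float) -> float:
    """F = 2*Sn*Pr / (Sn + Pr); 0 when both are 0."""
    return 0.0 if sn + pr == 0 else 2.0 * sn * pr / (sn + pr)


def evaluate(predicted_genes: set, target: set, covariate_gene_set: set | None = None) -> Metrics:
    """Sensitivity / precision / F of a predicted gene set against the target,
    with false positives split into covariate-related and extrinsic."""
    predicted = set(predicted_genes)
    target = set(target)
    covariate_gene_set = set(covariate_gene_set or ())
    tp = len(predicted & target)
    fp = len(predicted - target)
    fn = len(target - predicted)
    sn = tp / (tp + fn) if tp + fn else 0.0
    undefined = tp + fp == 0
    pr = 0.0 if undefined else tp / (tp + fp)
    fp_cov = len((predicted - target) & covariate_gene_set)
    return Metrics(
        sn=sn, pr=pr, f=f_value(sn, pr), tp=tp, fp=fp, fn=fn,
        fp_covariate=fp_cov, fp_extrinsic=fp - fp_cov,
        undefined_precision=undefined,
    )


def significant_genes_dsa(records, feature_gene: dict, q_cutoff=0.05, p_cutoff=0.05) -> set:
    return {
        feature_gene[r.intron_key]
        for r in records
        if r.q_value <= q_cutoff and r.p_value <= p_cutoff and r.intron_key in feature_gene
    }


def significant_genes_dsr(records, bunch_gene: dict, q_cutoff=0.05, p_cutoff=0.05) -> set:
    return {
        bunch_gene[r.bunch_id]
        for r in records
        if r.q_value <= q_cutoff and r.p_value <= p_cutoff and r.bunch_id in bunch_gene
    }
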