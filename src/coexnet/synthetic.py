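"""Planted-module synthetic data for end-to-end pipeline testing.

The generator emulates the study design the pipeline targets: two
independent expression datasets (defaults of 166 and 76 samples, the sizes
of the two lung cancer cell-line cohorts the method was developed on) that
share a latent-factor co-expression module containing the seed gene and a
designated hub regulator, plus an interaction edge list in which that
regulator is the star hub of the module.

Single-factor model: per sample s a latent z_s ~ N(0,1) is drawn; a module
gene g takes the value sign_g * beta_g * z_s + N(0, sigma^2), while
background genes are independent N(0,1). The population correlation between
two module genes then has the closed form

    r = sign_g sign_h beta_g beta_h / sqrt((beta_g^2+sigma^2)(beta_h^2+sigma^2))

so ground-truth correlations are known exactly and screen power can be
placed on either side of the |r| > 0.55 operating point by choosing the
loadings.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .ingest import ExpressionMatrix, FeatureAnnotation, InteractionEvidence


@dataclass(frozen=True)
class ModuleGene:
    symbol: str
    loading: float
    sign: int = 1


def loading_for_expected_r(r: float, noise_sd: float = 1.0) -> float:
    """Loading beta such that two module genes with equal loadings have
    population correlation r: beta = sigma * sqrt(r / (1 - r))."""
    if not 0.0 < r < 1.0:
        raise ValidationError("expected correlation must be in (0, 1)")
    return noise_sd * float(np.sqrt(r / (1.0 - r)))


@dataclass
class SynthSpec:
    """Full parameterization of the planted-module generator."""

    module: list[ModuleGene]
    seed_gene: str
    hub_gene: str
    n_background_genes: int = 5000
    noise_sd: float = 1.0
    n_samples_1: int = 166
    n_samples_2: int = 76
    background_edge_prob: float = 0.001
    rng_seed: int = 0

    def __post_init__(self) -> None:
        symbols = [g.symbol for g in self.module]
        if len(set(symbols)) != len(symbols):
            raise ValidationError("duplicate module gene symbols")
        if len(self.module) < 3:
            raise ValidationError("module must hold seed + hub + at least one gene")
        if self.seed_gene not in symbols or self.hub_gene not in symbols:
            raise ValidationError("module must contain the seed and hub genes")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        if not 0.0 <= self.background_edge_prob < 1.0:
            raise ValidationError("background_edge_prob must be in [0, 1)")
        if not all(np.isfinite(g.loading) for g in self.module):
            raise ValidationError("loadings must be finite")

    @property
    def module_symbols(self) -> list[str]:
        return [g.symbol for g in self.module]

    @property
    def background_symbols(self) -> list[str]:
        width = len(str(max(self.n_background_genes, 1)))
        return [f"BG{i:0{width}d}" for i in range(1, self.n_background_genes + 1)]

    @property
    def gene_ids(self) -> list[str]:
        return self.module_symbols + self.background_symbols

    @classmethod
    def default(
        cls,
        expected_r: float = 0.8,
        n_module: int = 20,
        n_background_genes: int = 5000,
        n_negative: int = 5,
        rng_seed: int = 0,
        **kwargs,
    ) -> "SynthSpec":
        """Study-condition defaults: a 20-gene module plus seed (GSK3B) and
        hub (ELAVL1) among 5000 background genes, equal loadings set for a
        chosen population |r| (default 0.8), with a subset of
        negative-loading members to exercise sign concordance."""
        beta = loading_for_expected_r(expected_r, kwargs.get("noise_sd", 1.0))
        module = [ModuleGene("GSK3B", beta, 1), ModuleGene("ELAVL1", beta, 1)]
        for i in range(1, n_module + 1):
            sign = -1 if i <= n_negative else 1
            module.append(ModuleGene(f"MOD{i:02d}", beta, sign))
        return cls(
            module=module,
            seed_gene="GSK3B",
            hub_gene="ELAVL1",
            n_background_genes=n_background_genes,
            rng_seed=rng_seed,
            **kwargs,
        )


@dataclass
class TruthTable:
    labels: dict[str, str]  # gene -> seed | module | background
    seed_gene: str
    hub_gene: str
    expected_r_to_seed: dict[str, float]  # module genes (incl. hub)

    def partition_ok(self) -> bool:
        return set(self.labels.values()) <= {"seed", "module", "background"}

    def module_genes(self) -> list[str]:
        """Module members excluding the seed itself (screen ground truth)."""
        return sorted(g for g, lab in self.labels.items() if lab == "module")


def expected_correlation(
    beta_g: float, beta_h: float, sign_g: int, sign_h: int, noise_sd: float
) -> float:
    """Population Pearson correlation of two module genes in the
    single-factor model."""
    if noise_sd <= 0:
        raise ValidationError("noise_sd must be > 0")
    s2 = noise_sd * noise_sd
    return (
        sign_g * sign_h * beta_g * beta_h
        / float(np.sqrt((beta_g**2 + s2) * (beta_h**2 + s2)))
    )


def truth_table(spec: SynthSpec) -> TruthTable:
    seed = next(g for g in spec.module if g.symbol == spec.seed_gene)
    expected = {
        g.symbol: expected_correlation(g.loading, seed.loading, g.sign, seed.sign, spec.noise_sd)
        for g in spec.module
        if g.symbol != spec.seed_gene
    }
    labels = {spec.seed_gene: "seed"}
    for g in spec.module:
        if g.symbol != spec.seed_gene:
            labels[g.symbol] = "module"
    for g in spec.background_symbols:
        labels[g] = "background"
    return TruthTable(
        labels=labels,
        seed_gene=spec.seed_gene,
        hub_gene=spec.hub_gene,
        expected_r_to_seed=expected,
    )


def _stream_rng(rng_seed: int, stream_label: str) -> np.random.Generator:
    """Independent, reproducible stream per (seed, label)."""
    return np.random.default_rng([rng_seed, zlib.crc32(stream_label.encode())])


def simulate_dataset(
    spec: SynthSpec, n_samples: int, stream_label: str
) -> tuple[ExpressionMatrix, TruthTable]:
    """Draw one expression dataset under the single-factor model."""
    if n_samples < 3:
        raise ValidationError("need at least 3 samples")
    rng = _stream_rng(spec.rng_seed, stream_label)
    z = rng.standard_normal(n_samples)
    n_mod = len(spec.module)
    signs = np.array([g.sign for g in spec.module], dtype=float)
    betas = np.array([g.loading for g in spec.module], dtype=float)
    module_vals = (
        signs[:, None] * betas[:, None] * z[None, :]
        + rng.normal(0.0, spec.noise_sd, size=(n_mod, n_samples))
    )
    background_vals = rng.standard_normal((spec.n_background_genes, n_samples))
    values = pd.DataFrame(
        np.vstack([module_vals, background_vals]),
        index=pd.Index(spec.gene_ids, name="feature_id"),
        columns=[f"S{stream_label}_{i:04d}" for i in range(1, n_samples + 1)],
    )
    expr = ExpressionMatrix(dataset_id=f"synthetic_{stream_label}", values=values)
    return expr, truth_table(spec)


def simulate_pair(
    spec: SynthSpec,
) -> tuple[ExpressionMatrix, ExpressionMatrix, TruthTable]:
    """Two independent cohorts sharing gene universe, loadings, and truth."""
    expr1, truth = simulate_dataset(spec, spec.n_samples_1, "A")
    expr2, _ = simulate_dataset(spec, spec.n_samples_2, "B")
    return expr1, expr2, truth


def simulate_evidence(spec: SynthSpec) -> InteractionEvidence:
    """Star edges hub <-> every other module gene (direct), plus seeded
    Erdos-Renyi background edges over the whole gene universe (indirect)."""
    ev = InteractionEvidence()
    for g in spec.module_symbols:
        if g != spec.hub_gene:
            ev.add(spec.hub_gene, g, "direct")
    p = spec.background_edge_prob
    if p > 0:
        rng = _stream_rng(spec.rng_seed, "evidence")
        genes = spec.gene_ids
        n = len(genes)
        # sample all C(n,2) pairs in one vectorized Bernoulli pass
        iu, ju = np.triu_indices(n, k=1)
        hits = rng.random(iu.size) < p
        for i, j in zip(iu[hits], ju[hits]):
            ev.add(genes[i], genes[j], "indirect")
    return ev


def annotation_for(spec: SynthSpec) -> FeatureAnnotation:
    """Identity feature->symbol annotation for synthetic datasets."""
    return FeatureAnnotation.identity(spec.gene_ids)


def write_truth_tsv(truth: TruthTable, path) -> None:
    with open(str(path), "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene\tlabel\tis_hub\texpected_r_to_seed\n")
        for gene in sorted(truth.labels):
            exp_r = truth.expected_r_to_seed.get(gene)
            fh.write(
                f"{gene}\t{truth.labels[gene]}\t{int(gene == truth.hub_gene)}\t"
                f"{'NA' if exp_r is None else repr(exp_r)}\n"
            )
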