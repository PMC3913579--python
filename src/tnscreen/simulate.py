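"""Synthetic mutant-library study generator with known ground truth.

Emulates the design of a high-throughput transposon-mutant metabolic
profiling study in *C. glutamicum*: a circular genome with ~87% coding
density, uniform transposon insertions, four relative-growth groups, and
GC/MS peak tables for wild-type samples (45 in total), six quality
standards and two blanks per experiment, and mutant triplicates spread over
several experiments. Every sample carries a ribitol internal-standard peak;
metabolites appear as 1–3 derivative peaks whose true areas sum to the
metabolite abundance; noise is multiplicative log-normal with
per-(metabolite, experiment) batch effects; planted fold-changes and
correlated metabolite blocks provide ground truth for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .annotation import GeneAnnotation, GeneRecord
from .peaks import INTERNAL_STANDARD

#: Default metabolite catalog (37 entries) modelled on what GC/MS profiling
#: of C. glutamicum reliably quantifies: TCA-cycle intermediates, glycolysis
#: intermediates, amino acids, fatty acids, and two unidentified substances
#: named by retention index.
DEFAULT_METABOLITES: tuple[str, ...] = (
    "citrate", "2-oxoglutarate", "succinate", "fumarate", "malate",
    "glucose-6-phosphate", "fructose-1,6-bisphosphate", "glycerate-3-phosphate",
    "phosphoenolpyruvate", "pyruvate",
    "glutamate", "glutamine", "proline", "N-acetyl-glutamate",
    "alanine", "aspartate", "glycine", "serine", "threonine", "valine",
    "leucine", "isoleucine", "lysine", "methionine", "phenylalanine", "tyrosine",
    "2,6-diaminopimelate", "homoserine", "trehalose", "AMP", "uracil",
    "ribose-5-phosphate",
    "tetradecanoate", "hexadecanoate", "octadecanoate",
    "NA_1705.4", "NA_1375.4",
)


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class CorrelatedBlock:
    """A group of metabolites sharing a log-scale latent factor.

    Each mutant g draws one factor z_g ~ N(0,1); every member metabolite m
    receives the mutant-level log effect
    ``scale * (sqrt(rho) * z_g + sqrt(1-rho) * eps_gm)``, so the pairwise
    correlation of true log effects between members equals ``rho`` and the
    marginal SD equals ``scale``. Observed log2-ratio correlations attenuate
    to ``rho * scale^2 / (scale^2 + s^2)`` where ``s^2`` is the sampling
    variance of the estimated log ratio.
    """

    members: tuple[str, ...]
    rho: float
    scale: float

    def __post_init__(self) -> None:
        if not (0 <= self.rho <= 1):
            raise ConfigurationError("block rho must be in [0, 1]")
        if self.scale < 0:
            raise ConfigurationError("block scale must be >= 0")


DEFAULT_BLOCKS: tuple[CorrelatedBlock, ...] = (
    CorrelatedBlock(("2-oxoglutarate", "succinate", "fumarate", "malate"), rho=0.7, scale=0.12),
    CorrelatedBlock(("glutamine", "proline", "NA_1705.4"), rho=0.6, scale=0.12),
    CorrelatedBlock(("tetradecanoate", "hexadecanoate", "octadecanoate"), rho=0.6, scale=0.10),
)


@dataclass(frozen=True)
class PlantedEffect:
    """Ground-truth fold change of one metabolite in one mutant."""

    mutant_id: str
    metabolite: str
    fold_change: float

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ConfigurationError("fold_change must be positive")


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic generator.

    Defaults mirror the emulated study: 45 wild-type samples, six quality
    standards per experiment, mutant triplicates, 258 mutants over seven
    experiments, 87% coding density, and a technical coefficient of
    variation of 11.5%.
    """

    genome_length: int = 3_282_708
    n_genes: int = 3000
    coding_density: float = 0.87
    hypothetical_fraction: float = 0.36
    operon_fraction: float = 0.55
    investigated_fraction: float = 0.11
    n_mutants: int = 258
    n_experiments: int = 7
    wt_samples_total: int = 45
    qc_per_experiment: int = 6
    blanks_per_experiment: int = 2
    mutant_replicates: int = 3
    n_metabolites: int = 37
    derivatives_per_metabolite: int = 3
    noise_cv: float = 0.115
    batch_sd: float = 0.2
    injection_sd: float = 0.2
    missing_rate: float = 0.02
    n_contaminants: int = 1
    n_low_coverage: int = 0
    low_coverage_rate: float = 0.3
    growth_group_probabilities: tuple[float, float, float, float] = (
        22 / 260, 29 / 260, 204 / 260, 5 / 260,
    )
    blocks: tuple[CorrelatedBlock, ...] = DEFAULT_BLOCKS
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.genome_length <= 0:
            raise ConfigurationError("genome_length must be positive")
        if self.n_genes < 0 or self.n_mutants < 0:
            raise ConfigurationError("n_genes and n_mutants must be non-negative")
        if not (0 < self.coding_density < 1):
            raise ConfigurationError("coding_density must be in (0, 1)")
        for name in ("hypothetical_fraction", "operon_fraction", "investigated_fraction",
                     "missing_rate", "low_coverage_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.n_experiments < 1 or self.wt_samples_total < 1:
            raise ConfigurationError("need >= 1 experiment and >= 1 wild-type sample")
        if self.qc_per_experiment < 1 or self.mutant_replicates < 1:
            raise ConfigurationError("qc_per_experiment and mutant_replicates must be >= 1")
        if self.n_metabolites < 1:
            raise ConfigurationError("n_metabolites must be >= 1")
        if not (1 <= self.derivatives_per_metabolite <= 3):
            raise ConfigurationError("derivatives_per_metabolite must be in [1, 3]")
        if self.noise_cv <= 0 or self.batch_sd < 0 or self.injection_sd < 0:
            raise ConfigurationError("noise_cv must be > 0; SDs must be >= 0")
        p = self.growth_group_probabilities
        if len(p) != 4 or any(x < 0 for x in p) or abs(sum(p) - 1.0) > 1e-9:
            raise ConfigurationError("growth_group_probabilities must be 4 non-negatives summing to 1")

    def metabolite_names(self) -> list[str]:
        if self.n_metabolites <= len(DEFAULT_METABOLITES):
            return list(DEFAULT_METABOLITES[: self.n_metabolites])
        extra = [f"metabolite_{i:03d}" for i in range(self.n_metabolites - len(DEFAULT_METABOLITES))]
        return list(DEFAULT_METABOLITES) + extra


def _rng(config_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=config_seed, spawn_key=(stream,)))


# ----------------------------------------------------------------- annotation


def gen_annotation(config: SimulationConfig) -> GeneAnnotation:
    """Generate non-overlapping genes on a circular genome at the target density.

    Gene lengths are gamma-distributed around the mean implied by
    ``coding_density * genome_length / n_genes`` and rescaled so that the
    realized coding fraction matches the configured density to rounding
    error. By default no gene wraps the origin.
    """
    L = config.genome_length
    if config.n_genes == 0:
        return GeneAnnotation(L, [])
    rng = _rng(config.seed, 1)
    target_coding = int(round(config.coding_density * L))
    mean_len = target_coding / config.n_genes
    if mean_len < 30 or target_coding >= L:
        raise ConfigurationError(
            f"infeasible annotation: {config.n_genes} genes cannot cover "
            f"{target_coding} bp of a {L} bp genome with realistic lengths"
        )
    lengths = rng.gamma(shape=6.0, scale=mean_len / 6.0, size=config.n_genes)
    lengths = np.maximum(lengths, 30.0)
    lengths = np.floor(lengths * target_coding / lengths.sum()).astype(np.int64)
    lengths = np.maximum(lengths, 30)
    lengths[-1] += target_coding - lengths.sum()  # absorb rounding drift
    if lengths[-1] < 30:
        raise ConfigurationError("infeasible density/gene-count combination")
    gap_total = L - int(lengths.sum())
    w = rng.random(config.n_genes) + 0.05
    gaps = np.floor(gap_total * w / w.sum()).astype(np.int64)
    gaps[-1] += gap_total - gaps.sum()
    strands = rng.choice(["+", "-"], size=config.n_genes)
    hypothetical = rng.random(config.n_genes) < config.hypothetical_fraction
    investigated = rng.random(config.n_genes) < config.investigated_fraction

    # operon membership: start an operon of 2-4 consecutive genes with a
    # probability tuned so the expected member fraction matches the config
    operon_ids: list[str | None] = [None] * config.n_genes
    mean_size = 3.0
    f = config.operon_fraction
    q = f / (mean_size * (1 - f) + f) if f < 1 else 1.0
    i, op = 0, 0
    while i < config.n_genes:
        if rng.random() < q:
            size = int(rng.integers(2, 5))
            op += 1
            for j in range(i, min(i + size, config.n_genes)):
                operon_ids[j] = f"op{op:04d}"
            i += size
        else:
            i += 1

    genes = []
    cursor = 1
    for k in range(config.n_genes):
        cursor += int(gaps[k])
        start = cursor
        end = start + int(lengths[k]) - 1
        genes.append(
            GeneRecord(
                locus=f"SCgl{k + 1:04d}",
                start=start,
                end=end,
                strand=str(strands[k]),
                description="hypothetical protein" if hypothetical[k] else f"enzyme {k + 1}",
                hypothetical=bool(hypothetical[k]),
                operon_id=operon_ids[k],
                investigated=bool(investigated[k]),
            )
        )
        cursor = end + 1
    return GeneAnnotation(L, genes)


# ------------------------------------------------------------------ insertions


def _well_ids(n: int) -> list[str]:
    """Plate/well-style mutant ids (P1A1 ... P1H12, P2A1, ...)."""
    ids = []
    for i in range(n):
        plate, rem = divmod(i, 96)
        row, col = divmod(rem, 12)
        ids.append(f"P{plate + 1}{'ABCDEFGH'[row]}{col + 1}")
    return ids


def gen_insertions(annotation: GeneAnnotation, config: SimulationConfig) -> pd.DataFrame:
    """Uniform random insertion positions over the whole genome, one per mutant."""
    if config.n_mutants < 0:
        raise ConfigurationError("n_mutants must be non-negative")
    rng = _rng(config.seed, 2)
    positions = rng.integers(1, annotation.genome_length + 1, size=config.n_mutants)
    return pd.DataFrame({"mutant_id": _well_ids(config.n_mutants), "position": positions})


def gen_growth(mutants: pd.DataFrame, config: SimulationConfig) -> pd.Series:
    """Relative growth (%OD after 7 h vs wild type) per mutant.

    Each mutant is assigned a growth group with the configured
    probabilities, then a %OD value uniform within the group's bin:
    minimal [0,40), reduced [40,80), similar [80,120], enhanced (120,160].
    """
    rng = _rng(config.seed, 3)
    n = len(mutants)
    if n == 0:
        return pd.Series(dtype=float, name="pct_od")
    groups = rng.choice(4, size=n, p=list(config.growth_group_probabilities))
    lo = np.array([5.0, 40.0, 80.0, 120.0])[groups]
    hi = np.array([40.0, 80.0, 120.0, 160.0])[groups]
    pct = lo + rng.random(n) * (hi - lo)
    # keep the group-similar closed upper bound representable
    pct = np.where(groups == 2, np.minimum(pct, 120.0), pct)
    return pd.Series(pct, index=list(mutants["mutant_id"]), name="pct_od")


# ------------------------------------------------------------------- peak data


@dataclass
class FixtureBundle:
    """In-memory synthetic study: peaks, metadata, derivative map, truth.

    ``abundances`` holds the sampled per-(metabolite, sample) true
    abundances before missingness was applied — the quantity the derivative
    peak areas of each metabolite must sum to.
    """

    peaks: pd.DataFrame
    sample_meta: pd.DataFrame
    derivative_map: dict[str, str]
    truth: pd.DataFrame
    abundances: pd.DataFrame | None = None


def _partition(total: int, parts: int) -> list[int]:
    base, rem = divmod(total, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]


def gen_peak_data(
    annotation: GeneAnnotation,
    mutants: pd.DataFrame,
    effects: Sequence[PlantedEffect],
    config: SimulationConfig,
    growth: pd.Series | None = None,
) -> FixtureBundle:
    """Generate per-sample GC/MS peak tables for the whole study design.

    Per experiment: that experiment's mutants in triplicate, a share of the
    wild-type samples, ``qc_per_experiment`` quality standards and blanks.
    True metabolite abundances are log-normal around per-metabolite base
    means, multiplied by planted fold changes, correlated-block effects,
    per-(metabolite, experiment) batch factors, culture OD and a per-sample
    injection factor that the internal standard shares (so it cancels on
    normalization). Metabolite abundance is split over 1-3 derivative peaks
    with fixed per-metabolite weights summing to one.
    """
    rng = _rng(config.seed, 4)
    mets = config.metabolite_names()
    met_index = {m: i for i, m in enumerate(mets)}
    mutant_ids = list(mutants["mutant_id"])
    mutant_index = {m: i for i, m in enumerate(mutant_ids)}

    bad = [e for e in effects if e.mutant_id not in mutant_index or e.metabolite not in met_index]
    if bad:
        offenders = ", ".join(f"({e.mutant_id}, {e.metabolite})" for e in bad)
        raise ConfigurationError(f"planted effects reference unknown mutants/metabolites: {offenders}")

    if growth is None:
        growth = gen_growth(mutants, config)

    # ---- sample layout -----------------------------------------------------
    E = config.n_experiments
    wt_share = _partition(config.wt_samples_total, E)
    mut_assignment = {m: i % E for i, m in enumerate(mutant_ids)}
    rows: list[dict] = []
    for e in range(E):
        exp = f"E{e + 1}"
        for r in range(wt_share[e]):
            rows.append(dict(sample_id=f"WT_{exp}_r{r + 1}", sample_type="wildtype",
                             mutant_id="", experiment_id=exp))
        for r in range(config.qc_per_experiment):
            rows.append(dict(sample_id=f"QC_{exp}_r{r + 1}", sample_type="quality_standard",
                             mutant_id="", experiment_id=exp))
        for r in range(config.blanks_per_experiment):
            rows.append(dict(sample_id=f"BL_{exp}_r{r + 1}", sample_type="blank",
                             mutant_id="", experiment_id=exp))
        for m in mutant_ids:
            if mut_assignment[m] != e:
                continue
            for r in range(config.mutant_replicates):
                rows.append(dict(sample_id=f"{m}_r{r + 1}", sample_type="mutant",
                                 mutant_id=m, experiment_id=exp))
    meta = pd.DataFrame(rows).set_index("sample_id")

    S = len(meta)
    M = len(mets)
    exp_idx = meta["experiment_id"].str.slice(1).astype(int).to_numpy() - 1
    is_blank = (meta["sample_type"] == "blank").to_numpy()
    is_qc = (meta["sample_type"] == "quality_standard").to_numpy()
    mut_of_sample = np.array(
        [mutant_index.get(m, -1) if m else -1 for m in meta["mutant_id"]], dtype=int
    )

    # culture optical densities: wild type around 0.1; mutants scaled by
    # their relative growth; quality standards are pooled extract (od = 1)
    od = np.full(S, np.nan)
    wt_mask = (meta["sample_type"] == "wildtype").to_numpy()
    od[wt_mask] = 0.1 * np.exp(rng.normal(0.0, 0.05, size=int(wt_mask.sum())))
    mut_mask = mut_of_sample >= 0
    pct = growth.reindex(meta.loc[mut_mask, "mutant_id"]).to_numpy()
    od[mut_mask] = np.maximum(
        0.1 * (pct / 100.0) * np.exp(rng.normal(0.0, 0.05, size=int(mut_mask.sum()))), 0.002
    )
    od[is_qc] = 1.0
    meta["od"] = od
    meta["pct_od"] = meta["mutant_id"].map(growth)

    # ---- true abundance model ---------------------------------------------
    sigma = math.sqrt(math.log1p(config.noise_cv**2))
    ln_mu = rng.uniform(math.log(1e3), math.log(1e6), size=M)
    batch = rng.normal(0.0, config.batch_sd, size=(E, M))

    G = len(mutant_ids)
    mut_log_effect = np.zeros((G, M))
    for block in config.blocks:
        members = [met_index[m] for m in block.members if m in met_index]
        if not members or block.scale == 0:
            continue
        z = rng.normal(size=G)
        for m in members:
            eps = rng.normal(size=G)
            mut_log_effect[:, m] += block.scale * (
                math.sqrt(block.rho) * z + math.sqrt(1.0 - block.rho) * eps
            )
    for e in effects:
        mut_log_effect[mutant_index[e.mutant_id], met_index[e.metabolite]] += math.log(e.fold_change)

    f_s = np.exp(rng.normal(0.0, config.injection_sd, size=S))
    noise = rng.normal(0.0, 1.0, size=(M, S))
    od_factor = np.where(np.isnan(od), 1.0, od)
    if G > 0:
        sample_effect = np.where(
            mut_of_sample[None, :] >= 0, mut_log_effect[mut_of_sample, :].T, 0.0
        )
    else:
        sample_effect = np.zeros((M, S))
    ln_v = (
        ln_mu[:, None]
        + batch[exp_idx, :].T
        + sample_effect
        + np.log(od_factor)[None, :]
        + np.log(f_s)[None, :]
        + sigma * noise
        - sigma**2 / 2.0
    )
    values = np.exp(ln_v)
    values[:, is_blank] = np.nan  # blanks carry no biological metabolites
    abundances = pd.DataFrame(values.copy(), index=mets, columns=meta.index)

    # missing-at-random per (metabolite, sample)
    miss = rng.random((M, S)) < config.missing_rate
    if config.n_low_coverage > 0:
        low = slice(M - config.n_low_coverage, M)
        miss[low, :] |= rng.random((config.n_low_coverage, S)) < config.low_coverage_rate
    values[miss] = np.nan

    # ---- derivative split --------------------------------------------------
    k_m = rng.integers(1, config.derivatives_per_metabolite + 1, size=M)
    ident_ri = 1150.0 + 38.0 * np.arange(M)  # arbitrary, well-separated grid
    peak_rows: list[pd.DataFrame] = []
    derivative_map: dict[str, str] = {INTERNAL_STANDARD: INTERNAL_STANDARD}
    sample_ids = np.array(meta.index)
    for i, met in enumerate(mets):
        unknown = met.startswith("NA_")
        k = 1 if unknown else int(k_m[i])
        weights = rng.dirichlet(np.full(k, 5.0)) if k > 1 else np.array([1.0])
        for j in range(k):
            area = values[i] * weights[j]
            present = np.isfinite(area)
            if unknown:
                true_ri = float(met[3:])
                ri = true_ri + rng.normal(0.0, 0.05, size=S)
                label = ""
            else:
                ri = np.full(S, ident_ri[i] + 3.0 * j)
                label = f"{met}_{j + 1}TMS"
                derivative_map[label] = met
            peak_rows.append(
                pd.DataFrame(
                    {
                        "sample_id": sample_ids[present],
                        "label": label,
                        "retention_index": np.round(ri[present], 3),
                        "area": area[present],
                    }
                )
            )

    # ribitol internal standard: fixed spike, scales only with injection
    peak_rows.append(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "label": INTERNAL_STANDARD,
                "retention_index": 1733.0,
                "area": 5.0e4 * f_s,
            }
        )
    )

    # contaminants: background peaks present in every sample including blanks
    for c in range(config.n_contaminants):
        level = math.exp(rng.uniform(math.log(1e3), math.log(1e4)))
        area = level * f_s * np.exp(sigma * rng.normal(size=S) - sigma**2 / 2)
        ri = 2051.7 + 37.0 * c + rng.normal(0.0, 0.05, size=S)
        peak_rows.append(
            pd.DataFrame(
                {
                    "sample_id": sample_ids,
                    "label": "",
                    "retention_index": np.round(ri, 3),
                    "area": area,
                }
            )
        )

    peaks = pd.concat(peak_rows, ignore_index=True)
    peaks = peaks.sort_values(["sample_id", "retention_index"], kind="mergesort").reset_index(drop=True)

    # ---- ground truth ------------------------------------------------------
    planted = {(e.mutant_id, e.metabolite): e.fold_change for e in effects}
    truth = pd.DataFrame(
        {
            "mutant_id": np.repeat(mutant_ids, M),
            "metabolite": np.tile(mets, G),
            "planted_fold_change": [
                planted.get((g, m), 1.0) for g in mutant_ids for m in mets
            ],
            "log2_fold_total": (mut_log_effect / math.log(2)).ravel(),
        }
    )
    return FixtureBundle(
        peaks=peaks,
        sample_meta=meta,
        derivative_map=derivative_map,
        truth=truth,
        abundances=abundances,
    )


# --------------------------------------------------------------- study effects


def default_effects(mutants: pd.DataFrame, config: SimulationConfig) -> list[PlantedEffect]:
    """Planted fold-change patterns emulating the screened study outcomes.

    Fifteen affected mutants: four with glutamate-associated changes only
    (one mirroring a glnE-type ammonium-assimilation lesion: glutamine 3.1,
    proline 2.3, glutamate 0.69, 2-oxoglutarate 0.69, aspartate 0.34), five
    with changes in both the TCA cycle and glutamate metabolites, and six
    with TCA-cycle changes only.
    """
    ids = list(mutants["mutant_id"])
    if len(ids) < 15:
        raise ConfigurationError("default effect set needs >= 15 mutants")
    mets = set(config.metabolite_names())

    def fx(mutant: str, spec: Mapping[str, float]) -> list[PlantedEffect]:
        return [
            PlantedEffect(mutant, met, fold)
            for met, fold in spec.items()
            if met in mets
        ]

    glu_only = [
        {"glutamine": 3.1, "proline": 2.3, "glutamate": 0.69, "2-oxoglutarate": 0.69,
         "aspartate": 0.34, "2,6-diaminopimelate": 2.5, "NA_1705.4": 2.9},
        {"glutamine": 8.0, "proline": 12.0, "N-acetyl-glutamate": 0.72},
        {"glutamine": 2.2, "glutamate": 1.8},
        {"proline": 3.0, "N-acetyl-glutamate": 0.4},
    ]
    dual = [
        {"proline": 10.0, "glutamine": 1.4, "glutamate": 1.5, "N-acetyl-glutamate": 0.07,
         "citrate": 1.3, "2-oxoglutarate": 0.61, "succinate": 0.60, "fumarate": 0.36,
         "malate": 0.33},
        {"succinate": 3.0, "fumarate": 3.2, "glutamine": 2.5, "proline": 2.0},
        {"malate": 0.4, "fumarate": 0.45, "glutamate": 0.5, "glutamine": 0.5},
        {"citrate": 2.0, "2-oxoglutarate": 2.2, "glutamate": 2.0, "proline": 1.8},
        {"succinate": 2.4, "malate": 2.1, "glutamine": 1.9, "N-acetyl-glutamate": 2.0},
    ]
    tca_only = [
        {"succinate": 1.4, "malate": 1.7, "fumarate": 1.4, "serine": 2.4, "glycine": 2.0},
        {"succinate": 0.5, "fumarate": 0.5},
        {"citrate": 1.8, "malate": 1.6},
        {"fumarate": 2.5, "malate": 2.4},
        {"succinate": 3.5, "fumarate": 3.0, "malate": 2.8},
        {"2-oxoglutarate": 0.45, "citrate": 0.5},
    ]
    out: list[PlantedEffect] = []
    for i, spec in enumerate(glu_only + dual + tca_only):
        out.extend(fx(ids[i], spec))
    return out


# ----------------------------------------------------------------- fixture I/O


def make_fixture(
    outdir: str | Path,
    config: SimulationConfig | None = None,
    effects: Sequence[PlantedEffect] | None = None,
    write_genome: bool = False,
) -> dict[str, Path]:
    """Generate and write a complete fixture bundle to ``outdir``.

    Writes annotation (GFF3), insertions + growth (TSV), one peak table per
    sample plus the sample-metadata TSV, derivative map, ground truth, and a
    YAML echo of the configuration. Returns the paths of the written files.
    """
    config = config or SimulationConfig()
    outdir = Path(outdir)
    (outdir / "peaks").mkdir(parents=True, exist_ok=True)

    annotation = gen_annotation(config)
    mutants = gen_insertions(annotation, config)
    growth = gen_growth(mutants, config)
    if effects is None:
        effects = default_effects(mutants, config) if config.n_mutants >= 15 else []
    bundle = gen_peak_data(annotation, mutants, effects, config, growth=growth)

    paths = {
        "annotation": outdir / "annotation.gff3",
        "insertions": outdir / "insertions.tsv",
        "growth": outdir / "growth.tsv",
        "sample_meta": outdir / "sample_meta.tsv",
        "derivative_map": outdir / "derivative_map.tsv",
        "truth": outdir / "truth.tsv",
        "config": outdir / "config.yaml",
        "peaks_dir": outdir / "peaks",
    }
    annotation.to_gff3(paths["annotation"])
    mutants.to_csv(paths["insertions"], sep="\t", index=False)
    growth.rename_axis("mutant_id").reset_index().to_csv(paths["growth"], sep="\t", index=False, float_format="%.4f")
    bundle.sample_meta.reset_index().to_csv(paths["sample_meta"], sep="\t", index=False, float_format="%.6g")
    pd.DataFrame(
        {"derivative": list(bundle.derivative_map), "metabolite": list(bundle.derivative_map.values())}
    ).to_csv(paths["derivative_map"], sep="\t", index=False)
    bundle.truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.6g")
    for sample_id, sub in bundle.peaks.groupby("sample_id", sort=True):
        sub[["label", "retention_index", "area"]].to_csv(
            outdir / "peaks" / f"{sample_id}.tsv", sep="\t", index=False, float_format="%.10g"
        )
    cfg_dict = asdict(config)
    cfg_dict["blocks"] = [
        {"members": list(b.members), "rho": b.rho, "scale": b.scale} for b in config.blocks
    ]
    cfg_dict["growth_group_probabilities"] = list(config.growth_group_probabilities)
    paths["config"].write_text(yaml.safe_dump(cfg_dict, sort_keys=True))

    if write_genome:
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord
        from Bio import SeqIO

        rng = _rng(config.seed, 9)
        seq = "".join(rng.choice(list("ACGT"), size=config.genome_length))
        rec = SeqRecord(Seq(seq), id="chromosome", description="synthetic circular genome")
        paths["genome"] = outdir / "genome.fasta"
        SeqIO.write([rec], paths["genome"], "fasta")
    return paths
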