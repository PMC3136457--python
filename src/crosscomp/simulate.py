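"""Seeded generator of multi-platform microarray collections with ground truth.

The generator plants regulon-like co-expression modules into a synthetic
compendium and, optionally, "un-normalizes" that truth back into raw
probe-level experiment files so the whole homogenization pipeline can be
exercised end to end against known answers.

The planted model: gene g's true log ratio in contrast c is

    t_gc = sum_m  beta_gm * a_mc

where beta_gm is a signed membership indicator (members of module m get
+1, anti-regulated members -1, non-members 0) and a_mc is module m's
activity in contrast c (zero outside its active contrasts, +-effect_size
with a random sign inside).  Background genes have t = 0.  The directly
generated compendium observes t + Gaussian noise with values masked
missing at a fixed rate.

The raw generator emulates what homogenization has to undo: log-normal
baseline intensities with a realistic dynamic range, per-platform gene
sensitivity multipliers, per-probe efficiencies, per-hybridization scale
factors, smooth intensity-dependent dye bias on dual-channel arrays, and
per-channel measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .compendium import LogratioCompendium
from .errors import ParameterError
from .ingest import ChannelInfo, ContrastDefinition, HybridizationTable

__all__ = [
    "PlantedModule",
    "SyntheticTruth",
    "PlatformSpec",
    "RawStudy",
    "generate_compendium",
    "generate_raw_experiments",
    "write_raw_study",
    "homogenization_study",
    "regulon_recovery_study",
    "meta_comparison_study",
]


@dataclass(frozen=True)
class PlantedModule:
    """Specification of one planted co-expression module."""

    size: int
    active_fraction: float
    effect_size: float  # log2 units
    anti_fraction: float = 0.0  # fraction of members with inverted sign
    name: str = ""


@dataclass
class SyntheticTruth:
    """Ground truth of a generated compendium."""

    membership: pd.Series  # gene -> module name ("" = background)
    member_sign: pd.Series  # gene -> +1 / -1 (sign of beta for members)
    activity: pd.DataFrame  # module x contrast activity a_mc (log2)
    true_logratios: pd.DataFrame  # noise-free t_gc
    contrast_meta: pd.DataFrame  # contrast -> experiment_id, platform_id
    noise_sd: float
    missing_rate: float
    seed: int

    def members_of(self, module_name: str) -> list[str]:
        return list(self.membership.index[self.membership == module_name])

    @property
    def background_genes(self) -> list[str]:
        return list(self.membership.index[self.membership == ""])


def generate_compendium(
    n_genes: int = 2000,
    n_experiments: int = 8,
    contrasts_per_experiment: int = 8,
    planted_modules: Sequence[PlantedModule] = (PlantedModule(30, 1 / 3, 1.5),),
    noise_sd: float = 0.3,
    missing_rate: float = 0.05,
    seed: int = 0,
    platforms: Sequence[str] = ("P1", "P2"),
) -> tuple[LogratioCompendium, SyntheticTruth]:
    """Directly generate a log-ratio compendium with planted modules.

    Observed values are ``t_gc + Normal(0, noise_sd)`` masked missing at
    ``missing_rate``.  Identical seed and parameters give identical
    output.
    """
    if n_genes <= 0 or n_experiments <= 0 or contrasts_per_experiment <= 0:
        raise ParameterError("sizes must be positive")
    total_planted = sum(m.size for m in planted_modules)
    if total_planted > n_genes:
        raise ParameterError("planted module sizes exceed n_genes")
    if not 0 <= missing_rate < 1:
        raise ParameterError("missing_rate must be in [0, 1)")

    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    contrasts, meta_rows = [], {}
    for e in range(n_experiments):
        exp = f"E{e + 1:02d}"
        plat = platforms[e % len(platforms)]
        for c in range(contrasts_per_experiment):
            cid = f"{exp}_c{c + 1:02d}"
            contrasts.append(cid)
            meta_rows[cid] = {"experiment_id": exp, "platform_id": plat}
    n_contrasts = len(contrasts)

    membership = pd.Series("", index=genes, dtype=object)
    member_sign = pd.Series(1.0, index=genes)
    module_names = []
    cursor = 0
    activity = pd.DataFrame(
        0.0, index=[], columns=contrasts
    )
    act_rows = {}
    for i, spec in enumerate(planted_modules):
        mod_name = spec.name or f"M{i + 1:02d}"
        module_names.append(mod_name)
        members = genes[cursor : cursor + spec.size]
        cursor += spec.size
        membership[members] = mod_name
        n_anti = int(round(spec.anti_fraction * spec.size))
        if n_anti:
            anti = rng.choice(members, size=n_anti, replace=False)
            member_sign[anti] = -1.0
        n_active = int(round(spec.active_fraction * n_contrasts))
        active = rng.choice(n_contrasts, size=n_active, replace=False)
        a = np.zeros(n_contrasts)
        a[active] = spec.effect_size * rng.choice([-1.0, 1.0], size=n_active)
        act_rows[mod_name] = a
    activity = pd.DataFrame(act_rows, index=contrasts).T
    if not module_names:
        activity = pd.DataFrame(np.empty((0, n_contrasts)), columns=contrasts)

    beta = np.zeros((n_genes, len(module_names)))
    for j, mod_name in enumerate(module_names):
        mask = (membership == mod_name).to_numpy()
        beta[mask, j] = member_sign.to_numpy()[mask]
    T = beta @ activity.to_numpy() if module_names else np.zeros((n_genes, n_contrasts))
    true_logratios = pd.DataFrame(
        T, index=pd.Index(genes, name="gene_id"), columns=contrasts
    )

    X = T + rng.normal(0.0, noise_sd, size=T.shape) if noise_sd > 0 else T.copy()
    if missing_rate > 0:
        mask = rng.random(size=X.shape) < missing_rate
        X = np.where(mask, np.nan, X)
    values = pd.DataFrame(X, index=genes, columns=contrasts)
    meta = pd.DataFrame.from_dict(meta_rows, orient="index")

    compendium = LogratioCompendium(values, meta, name=f"synthetic_seed{seed}")
    truth = SyntheticTruth(
        membership=membership,
        member_sign=member_sign,
        activity=activity,
        true_logratios=true_logratios,
        contrast_meta=meta,
        noise_sd=noise_sd,
        missing_rate=missing_rate,
        seed=seed,
    )
    return compendium, truth


# ---------------------------------------------------------------------------
# raw experiment generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlatformSpec:
    """Technology description of one synthetic platform."""

    platform_id: str
    channel_layout: str  # "single" | "dual"
    probes_per_gene: int = 3
    sensitivity_log2_sd: float = 0.5  # per-gene platform sensitivity spread
    probe_efficiency_log2_sd: float = 0.3
    hyb_scale_log2_sd: float = 0.3  # per-hybridization global scale


@dataclass
class RawStudy:
    """Raw probe-level experiment files plus everything ingest needs."""

    hybridizations: list[HybridizationTable]
    contrast_definitions: list[ContrastDefinition]
    probe_annotations: dict[str, pd.DataFrame]  # platform -> probe table
    gene_index: list[str]
    truth: SyntheticTruth
    dye_bias_amplitude: float = 0.0


def generate_raw_experiments(
    truth: SyntheticTruth,
    platform_specs: Sequence[PlatformSpec],
    dye_bias_amplitude: float = 0.0,
    noise_sd: float | None = None,
    missing_rate: float | None = None,
    probe_jitter_log2_sd: float = 0.1,
    baseline_median: float = 1000.0,
    baseline_log2_sd: float = 1.5,
    seed: int | None = None,
) -> RawStudy:
    """Emit raw hybridization tables realizing a truth's log ratios.

    Experiments are assigned to platforms round-robin in experiment order.
    Dual-channel experiments emit one array per contrast (channel 1 =
    reference, channel 2 = test); single-channel experiments emit one
    shared reference hybridization plus one test hybridization per
    contrast.  Reference expression per gene is a log-normal baseline
    (median ``baseline_median`` arbitrary units, log2 sd
    ``baseline_log2_sd``) scaled by a per-platform per-gene sensitivity;
    test expression multiplies in ``2**(t_gc + noise)``, where the noise
    realizes the truth's contrast-level ``noise_sd`` (the sd of observed
    log ratios around the planted truth, matching the direct generator's
    noise model).  Probe values jitter around gene values via fixed
    per-probe efficiencies plus per-measurement jitter of
    ``probe_jitter_log2_sd``; dual-channel arrays additionally receive a
    smooth intensity-dependent distortion of M with the given amplitude
    (emulating dye bias).
    """
    if not platform_specs:
        raise ParameterError("need at least one platform spec")
    for spec in platform_specs:
        if spec.channel_layout not in ("single", "dual"):
            raise ParameterError(f"bad channel layout {spec.channel_layout!r}")
        if spec.probes_per_gene < 1:
            raise ParameterError("probes_per_gene must be >= 1")
    noise = truth.noise_sd if noise_sd is None else noise_sd
    missing = truth.missing_rate if missing_rate is None else missing_rate
    rng = np.random.default_rng(truth.seed + 100003 if seed is None else seed)

    genes = list(truth.true_logratios.index)
    n_genes = len(genes)
    baseline = baseline_median * 2.0 ** rng.normal(0.0, baseline_log2_sd, size=n_genes)

    # per-platform structures
    sensitivity: dict[str, np.ndarray] = {}
    probe_tables: dict[str, pd.DataFrame] = {}
    probe_eff: dict[str, np.ndarray] = {}
    probe_gene_idx: dict[str, np.ndarray] = {}
    for spec in platform_specs:
        sensitivity[spec.platform_id] = 2.0 ** rng.normal(
            0.0, spec.sensitivity_log2_sd, size=n_genes
        )
        reps = spec.probes_per_gene
        probe_ids = [
            f"{spec.platform_id}:{g}:{r + 1:02d}" for g in genes for r in range(reps)
        ]
        gene_idx = np.repeat(np.arange(n_genes), reps)
        probe_tables[spec.platform_id] = pd.DataFrame(
            {
                "probe_id": probe_ids,
                "locus_tag": [genes[i] for i in gene_idx],
            }
        )
        probe_eff[spec.platform_id] = 2.0 ** rng.normal(
            0.0, spec.probe_efficiency_log2_sd, size=len(probe_ids)
        )
        probe_gene_idx[spec.platform_id] = gene_idx

    experiments = list(dict.fromkeys(truth.contrast_meta["experiment_id"]))
    exp_platform = {
        exp: platform_specs[i % len(platform_specs)] for i, exp in enumerate(experiments)
    }

    def probe_intensities(plat: str, gene_log2: np.ndarray) -> np.ndarray:
        """Probe-level log2 values around per-gene log2 values."""
        gidx = probe_gene_idx[plat]
        vals = gene_log2[gidx] + np.log2(probe_eff[plat])
        if probe_jitter_log2_sd > 0:
            vals = vals + rng.normal(0.0, probe_jitter_log2_sd, size=vals.shape)
        return vals

    def contrast_noise() -> np.ndarray:
        """Per-gene realization noise of one test condition (log2)."""
        if noise > 0:
            return rng.normal(0.0, noise, size=n_genes)
        return np.zeros(n_genes)

    def maybe_mask(values: np.ndarray) -> np.ndarray:
        if missing > 0:
            m = rng.random(size=values.shape) < missing
            return np.where(m, np.nan, values)
        return values

    hybridizations: list[HybridizationTable] = []
    definitions: list[ContrastDefinition] = []
    for exp in experiments:
        spec = exp_platform[exp]
        plat = spec.platform_id
        contrasts = list(
            truth.contrast_meta.index[truth.contrast_meta["experiment_id"] == exp]
        )
        probes = probe_tables[plat]["probe_id"].to_numpy()
        ref_gene_log2 = np.log2(baseline * sensitivity[plat])

        if spec.channel_layout == "dual":
            for cid in contrasts:
                t = truth.true_logratios[cid].to_numpy()
                scale1 = rng.normal(0.0, spec.hyb_scale_log2_sd)
                scale2 = rng.normal(0.0, spec.hyb_scale_log2_sd)
                ch1 = probe_intensities(plat, ref_gene_log2) + scale1
                ch2 = probe_intensities(plat, ref_gene_log2 + t + contrast_noise()) + scale2
                if dye_bias_amplitude != 0.0:
                    A = (ch1 + ch2) / 2.0
                    ch2 = ch2 + dye_bias_amplitude * (A - np.nanmean(A))
                hyb_id = f"{exp}_{cid.split('_')[-1]}_array"
                intens = pd.DataFrame(
                    {
                        "ch1": maybe_mask(2.0**ch1),
                        "ch2": maybe_mask(2.0**ch2),
                    },
                    index=probes,
                )
                hybridizations.append(
                    HybridizationTable(
                        experiment_id=exp,
                        platform_id=plat,
                        hybridization_id=hyb_id,
                        channel_layout="dual",
                        intensities=intens,
                        channels={
                            "ch1": ChannelInfo(sample_id=f"{cid}_ref", role="reference"),
                            "ch2": ChannelInfo(sample_id=f"{cid}_test", role="test"),
                        },
                    )
                )
                definitions.append(
                    ContrastDefinition(
                        contrast_id=cid,
                        experiment_id=exp,
                        platform_id=plat,
                        test_members=((hyb_id, "ch2"),),
                        reference_members=((hyb_id, "ch1"),),
                    )
                )
        else:
            ref_id = f"{exp}_ref"
            scale = rng.normal(0.0, spec.hyb_scale_log2_sd)
            ref_vals = probe_intensities(plat, ref_gene_log2) + scale
            hybridizations.append(
                HybridizationTable(
                    experiment_id=exp,
                    platform_id=plat,
                    hybridization_id=ref_id,
                    channel_layout="single",
                    intensities=pd.DataFrame(
                        {"ch1": maybe_mask(2.0**ref_vals)}, index=probes
                    ),
                    channels={"ch1": ChannelInfo(sample_id=f"{exp}_reference", role="reference")},
                )
            )
            for cid in contrasts:
                t = truth.true_logratios[cid].to_numpy()
                scale = rng.normal(0.0, spec.hyb_scale_log2_sd)
                vals = probe_intensities(plat, ref_gene_log2 + t + contrast_noise()) + scale
                hyb_id = f"{exp}_{cid.split('_')[-1]}_test"
                hybridizations.append(
                    HybridizationTable(
                        experiment_id=exp,
                        platform_id=plat,
                        hybridization_id=hyb_id,
                        channel_layout="single",
                        intensities=pd.DataFrame(
                            {"ch1": maybe_mask(2.0**vals)}, index=probes
                        ),
                        channels={"ch1": ChannelInfo(sample_id=f"{cid}_test", role="test")},
                    )
                )
                definitions.append(
                    ContrastDefinition(
                        contrast_id=cid,
                        experiment_id=exp,
                        platform_id=plat,
                        test_members=((hyb_id, "ch1"),),
                        reference_members=((ref_id, "ch1"),),
                    )
                )

    return RawStudy(
        hybridizations=hybridizations,
        contrast_definitions=definitions,
        probe_annotations=probe_tables,
        gene_index=genes,
        truth=truth,
        dye_bias_amplitude=dye_bias_amplitude,
    )


def write_raw_study(study: RawStudy, directory) -> None:
    """Write a raw study as the TSV files the ingest pipeline consumes."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for plat, table in study.probe_annotations.items():
        table.to_csv(directory / f"probes_{plat}.tsv", sep="\t", index=False)
    hyb_meta = []
    for h in study.hybridizations:
        h.intensities.to_csv(
            directory / f"intensities_{h.hybridization_id}.tsv",
            sep="\t",
            na_rep="NA",
            index_label="probe_id",
        )
        for ch, info in h.channels.items():
            hyb_meta.append(
                {
                    "experiment_id": h.experiment_id,
                    "platform_id": h.platform_id,
                    "hybridization_id": h.hybridization_id,
                    "channel_layout": h.channel_layout,
                    "channel": ch,
                    "sample_id": info.sample_id,
                    "role": info.role or "",
                    "biological": info.biological,
                }
            )
    pd.DataFrame(hyb_meta).to_csv(directory / "hybridizations.tsv", sep="\t", index=False)
    rows = [
        {
            "contrast_id": d.contrast_id,
            "experiment_id": d.experiment_id,
            "platform_id": d.platform_id,
            "test_members": ";".join(f"{h}|{c}" for h, c in d.test_members),
            "reference_members": ";".join(f"{h}|{c}" for h, c in d.reference_members),
        }
        for d in study.contrast_definitions
    ]
    pd.DataFrame(rows).to_csv(directory / "contrasts.tsv", sep="\t", index=False)
    pd.Series(study.gene_index, name="gene_id").to_csv(
        directory / "gene_index.tsv", sep="\t", index=False
    )
    study.truth.true_logratios.to_csv(
        directory / "truth_logratios.tsv", sep="\t", na_rep="NA", index_label="gene_id"
    )
    study.truth.membership.rename("module").to_csv(
        directory / "truth_membership.tsv", sep="\t", index_label="gene_id"
    )


# ---------------------------------------------------------------------------
# canned study conditions
# ---------------------------------------------------------------------------


def homogenization_study(seed: int = 0, dye_bias_amplitude: float = 0.5) -> RawStudy:
    """Raw multi-platform study used to validate end-to-end homogenization.

    2000 genes with twenty planted 50-gene modules over 8 experiments x 6
    contrasts, realized on two dual-channel and two single-channel
    platforms with contrast-level log2 noise 0.3 and the given dye-bias
    amplitude.  Regulon-sized (50-gene) modules with effect sizes between
    1.5 and 3 log2 units (3- to 8-fold, the physiological range of strong
    bacterial stress and regulon responses), each active in 30% of the
    contrasts: any single contrast then perturbs a moderate fraction of
    genes with roughly sign-balanced changes, so the "most genes
    unchanged" assumption behind loess and quantile normalization holds
    as it does in real compendia.  Dual platforms model spotted arrays
    (2 probes per gene); single-channel platforms model high-density
    oligonucleotide arrays (8 probes per gene, wider probe-affinity
    spread).
    """
    effects = (1.5, 1.5, 2.0, 2.0, 2.0, 2.0, 2.5, 2.5, 2.5, 3.0) * 2
    _, truth = generate_compendium(
        n_genes=2000,
        n_experiments=8,
        contrasts_per_experiment=6,
        planted_modules=tuple(
            PlantedModule(50, 0.3, e, name=f"M{i + 1:02d}")
            for i, e in enumerate(effects)
        ),
        noise_sd=0.3,
        missing_rate=0.0,
        seed=seed,
    )
    specs = (
        PlatformSpec("D1", "dual", probes_per_gene=2),
        PlatformSpec("D2", "dual", probes_per_gene=2, sensitivity_log2_sd=0.8),
        PlatformSpec("S1", "single", probes_per_gene=8, probe_efficiency_log2_sd=0.5),
        PlatformSpec(
            "S2",
            "single",
            probes_per_gene=8,
            probe_efficiency_log2_sd=0.5,
            sensitivity_log2_sd=0.8,
        ),
    )
    return generate_raw_experiments(
        truth, specs, dye_bias_amplitude=dye_bias_amplitude, missing_rate=0.0
    )


def regulon_recovery_study(
    seed: int = 0,
) -> tuple[LogratioCompendium, SyntheticTruth]:
    """Compendium with one planted 30-gene regulon for recovery testing.

    |effect| 1.5 log2 units in one third of 60 contrasts, noise sd 0.3,
    5% missing values, 1970 background genes.
    """
    return generate_compendium(
        n_genes=2000,
        n_experiments=6,
        contrasts_per_experiment=10,
        planted_modules=(PlantedModule(30, 1 / 3, 1.5, name="regulon"),),
        noise_sd=0.3,
        missing_rate=0.05,
        seed=seed,
    )


def meta_comparison_study(
    seed: int = 0,
) -> tuple[LogratioCompendium, SyntheticTruth]:
    """Heterogeneous 8-experiment compendium for the meta-analysis contrast.

    A 30-gene target regulon active in half of 56 contrasts plus fifteen
    30-gene confounder modules each active in a quarter of the contrasts;
    noise sd 0.3, 5% missing.  Individual experiments survey only 7
    contrasts, so per-experiment co-expression is poorly constrained —
    the condition the comparison is designed to expose.
    """
    modules = [PlantedModule(30, 0.5, 1.5, name="target")] + [
        PlantedModule(30, 0.25, 1.5, name=f"conf{i + 1:02d}") for i in range(15)
    ]
    return generate_compendium(
        n_genes=2000,
        n_experiments=8,
        contrasts_per_experiment=7,
        planted_modules=tuple(modules),
        noise_sd=0.3,
        missing_rate=0.05,
        seed=seed,
    )
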