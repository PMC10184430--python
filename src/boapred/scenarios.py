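"""End-to-end driver: simulate once, fit every method, evaluate.

The scenario grid mirrors a purebred-only reference for the within-breed
evaluations (BPM/BOM) plus a series of multi-breed references that add an
increasing number of crossbred animals for the BOA (and joint) models.
Scenario sizes default to the production ratios scaled down by a factor
of 20 (purebreds ~1000, crossbreds ~220/410/920); the crossbred subsets
are nested, so a larger scenario strictly extends a smaller one.

All randomness flows from two named seeds (the simulation seed inside
``SimConfig`` and the scenario seed); a run's manifest (config echo +
seeds) suffices to reproduce it bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .breedorigin import (
    breed_allele_freqs,
    build_partial_genotypes,
    center_genotypes,
    genomic_breed_proportions,
)
from .evaluate import (
    evaluation_report,
    group_by_main_breed_proportion,
    split_reference_validation,
)
from .mcmc import (
    BoaPriors,
    CovariancePrior,
    McmcSettings,
    VariancePrior,
    fit_boa,
    fit_joint,
    fit_within_breed,
    heuristic_variances,
    pilot_variances,
)
from .predict import predict_boa, predict_bom, predict_bpm, predict_joint
from .simulate import SimConfig, SyntheticDataset, default_design, simulate

logger = logging.getLogger(__name__)


@dataclass
class ScenarioConfig:
    """Reference compositions and fitting options for one scenario grid.

    ``crossbred_reference_sizes`` must be nondecreasing; each size labels
    one BOA/joint scenario (the purebred reference is shared).  The
    default sizes are the production crossbred counts divided by 20.
    """

    crossbred_reference_sizes: tuple[int, ...] = (221, 412, 919)
    methods: tuple[str, ...] = ("BPM", "BOM", "BOA_UNCOR", "BOA_COR")
    settings: McmcSettings = field(default_factory=McmcSettings.desk)
    pilot_settings: McmcSettings = field(default_factory=lambda: McmcSettings(600, 100, 5))
    n_boot: int = 2_000
    n_validation_crossbred: int = 420
    purebred_validation_fraction: float = 0.15
    threshold_year: int = 2018
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = self.crossbred_reference_sizes
        if len(sizes) == 0 or any(s < 1 for s in sizes):
            raise ValueError("crossbred reference sizes must be positive")
        if any(b < a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("crossbred reference sizes must be nondecreasing")
        unknown = set(self.methods) - {"BPM", "BOM", "BOA_UNCOR", "BOA_COR", "JOINT"}
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")

    def scenario_label(self, size: int) -> str:
        return f"P+{size}C"


@dataclass
class ScenarioResults:
    """Everything a scenario run produces."""

    summary: pd.DataFrame  # scenario x method x group predictive abilities / slopes
    comparisons: pd.DataFrame
    dataset: SyntheticDataset
    reference_ids: dict[str, list[str]]  # per scenario label
    validation_ids: list[str]
    manifest: dict


def _build_population(sim: SimConfig, scen: ScenarioConfig) -> SyntheticDataset:
    n_ref_cross = max(scen.crossbred_reference_sizes)
    design = default_design(n_ref=n_ref_cross + 12, n_val=scen.n_validation_crossbred)
    sim = dataclasses.replace(sim, crossbred_design=design)
    ds = simulate(sim)
    # Late-born purebreds form the purebred validation set (year rule:
    # founders have no recorded sire).
    ped = ds.pedigree
    n_val_pure = int(round(scen.purebred_validation_fraction * sim.n_purebred_per_breed))
    if n_val_pure:
        for label in sim.breeds:
            ids = ped.index[(ped["breed_label"] == label) & ped["is_purebred"]]
            ped.loc[ids[-n_val_pure:], "birth_year"] = scen.threshold_year + 1
    return ds


def run_scenarios(
    sim_config: SimConfig,
    scenario_config: ScenarioConfig,
    out_dir: str | Path | None = None,
) -> ScenarioResults:
    """Simulate once, then fit and evaluate every requested scenario.

    A failing scenario is logged and skipped; the others continue.
    """
    scen = scenario_config
    t0 = time.perf_counter()
    ds = _build_population(sim_config, scen)
    genos, origins, ped = ds.genotypes, ds.origins, ds.pedigree
    y = ds.adjusted_phenotypes
    breeds = sim_config.breeds
    rng = np.random.default_rng(scen.seed)
    chain_seed = lambda: int(rng.integers(2**31))  # noqa: E731

    split = split_reference_validation(ped, threshold_year=scen.threshold_year)
    pos = {a: i for i, a in enumerate(genos.animal_ids)}
    ref_ids = set(split.reference)
    is_pure = dict(zip(ped["animal"], ped["is_purebred"]))
    breed_of = dict(zip(ped["animal"], ped["breed_label"]))
    ref_pure_idx = np.array([pos[a] for a in split.reference if is_pure[a]])
    ref_cross = [a for a in split.reference if not is_pure[a]]
    val_idx = np.array([pos[a] for a in split.validation])
    val_ids = [genos.animal_ids[i] for i in val_idx]
    logger.info(
        "population: %d animals (%d reference, %d validation); %d markers",
        genos.n_animals, len(split.reference), len(split.validation), genos.n_markers,
    )

    # Nested crossbred reference subsets.
    order = rng.permutation(len(ref_cross))
    shuffled_cross = [ref_cross[i] for i in order]
    X_all = genomic_breed_proportions(origins)

    # ---- within-breed fits (purebred references), shared by BPM and BOM
    within_fits = {}
    need_within = {"BPM", "BOM"} & set(scen.methods)
    if need_within:
        for k, label in enumerate(breeds):
            sub = np.array([pos[a] for a in split.reference if is_pure[a] and breed_of[a] == label])
            Zc = center_genotypes(genos, sub)
            s2u0, s2e0 = heuristic_variances(y[sub], Zc.Z[sub])
            pilot = fit_within_breed(
                y[sub], Zc.Z[sub], VariancePrior(s2u0), VariancePrior(s2e0),
                dataclasses.replace(scen.pilot_settings, seed=chain_seed()),
            )
            fit = fit_within_breed(
                y[sub],
                Zc.Z[sub],
                VariancePrior(float(pilot.variance_samples["sigma2_u"].mean())),
                VariancePrior(float(pilot.variance_samples["sigma2_e"].mean())),
                dataclasses.replace(scen.settings, seed=chain_seed()),
            )
            fit.centering_freqs = Zc.freqs
            within_fits[label] = fit
        freqs_pure = breed_allele_freqs(genos, origins, ref_pure_idx)
        partials_pure = build_partial_genotypes(genos, origins, freqs_pure, breeds)

    summaries: list[pd.DataFrame] = []
    comparisons: list[pd.DataFrame] = []
    reference_ids: dict[str, list[str]] = {}
    for size in scen.crossbred_reference_sizes:
        label = scen.scenario_label(size)
        try:
            ref_s = sorted(
                [a for a in split.reference if is_pure[a]] + shuffled_cross[:size],
                key=pos.get,
            )
            reference_ids[label] = ref_s
            ref_s_idx = np.array([pos[a] for a in ref_s])
            pgms: dict[str, np.ndarray] = {}
            if "BPM" in scen.methods:
                val_genos_pgm = predict_bpm(
                    within_fits, genos, X_all, breeds
                )
                pgms["BPM"] = val_genos_pgm["pgm"].to_numpy()[val_idx]
            if "BOM" in scen.methods:
                bom = predict_bom(within_fits, partials_pure.subset(val_idx), val_ids)
                pgms["BOM"] = bom["pgm"].to_numpy()
            if {"BOA_UNCOR", "BOA_COR"} & set(scen.methods):
                freqs_s = breed_allele_freqs(genos, origins, ref_s_idx)
                partials_s = build_partial_genotypes(genos, origins, freqs_s, breeds)
                ref_parts = partials_s.subset(ref_s_idx)
                val_parts = partials_s.subset(val_idx)
                pilot = pilot_variances(
                    y[ref_s_idx], ref_parts.X, ref_parts,
                    dataclasses.replace(scen.pilot_settings, seed=chain_seed()),
                )
                snp_priors = [VariancePrior(float(v)) for v in pilot.sigma2_u]
                res_prior = VariancePrior(pilot.sigma2_e)
                for mode, mlabel in (("uncorrelated", "BOA_UNCOR"), ("correlated", "BOA_COR")):
                    if mlabel not in scen.methods:
                        continue
                    priors = BoaPriors(
                        snp=snp_priors,
                        residual=res_prior,
                        covariance=CovariancePrior(pilot.B_old) if mode == "correlated" else None,
                    )
                    fit = fit_boa(
                        y[ref_s_idx], ref_parts.X, ref_parts, mode, priors,
                        dataclasses.replace(scen.settings, seed=chain_seed()),
                    )
                    pgms[mlabel] = predict_boa(fit, val_parts, val_ids)["pgm"].to_numpy()
            if "JOINT" in scen.methods:
                Zc = center_genotypes(genos, ref_s_idx)
                s2u0, s2e0 = heuristic_variances(y[ref_s_idx], Zc.Z[ref_s_idx])
                jfit = fit_joint(
                    y[ref_s_idx], X_all[ref_s_idx], Zc.Z[ref_s_idx],
                    VariancePrior(s2u0), VariancePrior(s2e0),
                    dataclasses.replace(scen.settings, seed=chain_seed()),
                    breeds=breeds,
                )
                jfit.centering_freqs = Zc.freqs
                pgms["JOINT"] = predict_joint(jfit, genos, X_all)["pgm"].to_numpy()[val_idx]

            groups = _validation_groups(val_ids, is_pure, breed_of, X_all[val_idx])
            for grouping in groups:
                rep = evaluation_report(
                    y[val_idx], pgms, grouping, n_boot=scen.n_boot, seed=scen.seed
                )
                for key in ("summary", "comparisons"):
                    rep[key].insert(0, "scenario", label)
                summaries.append(rep["summary"])
                comparisons.append(rep["comparisons"])
        except Exception:
            logger.exception("scenario %s failed; continuing", label)
            continue

    summary = pd.concat(summaries, ignore_index=True) if summaries else pd.DataFrame()
    comps = pd.concat(comparisons, ignore_index=True) if comparisons else pd.DataFrame()
    manifest = {
        "boapred_version": __version__,
        "sim_config": _config_echo(sim_config),
        "scenario_config": _config_echo(scen),
        "n_animals": genos.n_animals,
        "n_reference": len(split.reference),
        "n_validation": len(split.validation),
        "elapsed_s": round(time.perf_counter() - t0, 2),
    }
    results = ScenarioResults(
        summary=summary,
        comparisons=comps,
        dataset=ds,
        reference_ids=reference_ids,
        validation_ids=val_ids,
        manifest=manifest,
    )
    if out_dir is not None:
        _write_outputs(Path(out_dir), results)
    return results


def _validation_groups(val_ids, is_pure, breed_of, X_val) -> list[np.ndarray]:
    """Two partitions of the validation set: pure/cross, and bp groups."""
    coarse = np.array(
        [f"Pure-{breed_of[a]}" if is_pure[a] else "Crossbred" for a in val_ids]
    )
    bp = group_by_main_breed_proportion(X_val)
    fine = np.where(coarse == "Crossbred", bp, coarse)
    return [coarse, fine]


def _config_echo(cfg) -> dict:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return str(o)

    return json.loads(json.dumps(dataclasses.asdict(cfg), default=default))


def _write_outputs(out: Path, results: ScenarioResults) -> None:
    out.mkdir(parents=True, exist_ok=True)
    results.summary.to_csv(out / "summary.csv", index=False)
    results.comparisons.to_csv(out / "comparisons.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(results.manifest, indent=2))
    with (out / "report.txt").open("w") as fh:
        fh.write("Predictive ability and dispersion slope by scenario\n")
        fh.write("=" * 55 + "\n")
        if not results.summary.empty:
            piv = results.summary.pivot_table(
                index=["group", "method"], columns="scenario",
                values="predictive_ability",
            )
            fh.write(piv.round(3).to_string() + "\n\n")
            piv_s = results.summary.pivot_table(
                index=["group", "method"], columns="scenario", values="slope"
            )
            fh.write("Slopes (y* on PGM)\n" + piv_s.round(3).to_string() + "\n")
    logger.info("wrote scenario reports to %s", out)
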