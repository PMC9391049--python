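"""End-to-end orchestration: chemistry -> recovery -> thermodynamics -> community.

:func:`run_pipeline` consumes a :class:`RunConfig` (optionally loaded from a
YAML file), either reads measurement/count tables from disk or generates them
with the synthetic module, and writes a bundle of TSV/JSON reports:

* ``concentrations.tsv`` — replicate-mean mM and µmol/gdw per analyte/day,
* ``rates.json`` — OLS consumption/production rates for H2 streams,
* ``recovery.tsv`` — electron-recovery table (per-period rows plus the
  consumption-weighted full-period row), one-decimal report rounding with a
  full-precision companion ``recovery_raw.tsv``,
* ``delta_g.tsv`` — in-situ dG per reaction/treatment/replicate/day with
  feasibility classification (undefined where H2 is censored),
* ``stimulation.tsv`` — the per-phylotype three-criterion verdict table,
* ``bray_curtis_<marker>.tsv`` — square distance matrices,
* ``screen.tsv`` — root-treatment abundance-screened features (when root
  treatments are configured),
* ``manifest.json`` — inputs, seed, thresholds, package version, row counts
  and aggregated warnings.

Every numeric output is produced by the other modules; this layer only
routes tables.  Outputs are written atomically (tmp + rename) so a crashed
run never leaves a truncated table behind a complete-looking name.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, chemistry, community, io, recovery, simulate, thermo
from .chemistry import VesselSpec
from .constants import DEFAULT_CONSTANTS, load_constants


@dataclass
class RunConfig:
    """Everything a run needs; round-trips losslessly through YAML."""

    seed: int = 0
    outdir: str = "fenflux_out"
    # inputs: either paths or synthetic generation
    measurements_path: str | None = None
    counts_path: str | None = None
    sample_meta_path: str | None = None
    fasta_path: str | None = None
    simulate_chemistry: bool = True
    simulate_community: bool = True
    constants_path: str | None = None
    # design
    pairings: list[list[str]] = field(default_factory=lambda: [["SH", "SU"]])
    periods: list[list[float]] = field(default_factory=lambda: [[0.0, 7.0], [7.0, 17.0]])
    root_treatments: list[str] = field(default_factory=list)
    markers: list[str] = field(default_factory=lambda: list(community.MARKERS))
    # thresholds
    p_max: float = community.DEFAULT_P_MAX
    lda_min: float = community.DEFAULT_LDA_MIN
    ratio_min: float = community.DEFAULT_RATIO_MIN
    rrna_min_pct: float = 1.0
    gene_min_pct: float = 0.5
    detection_limit_ppmv: float = 10.0
    denominator_floor: float = recovery.DEFAULT_DENOMINATOR_FLOOR
    n_boot: int = 30
    # vessel / conditions
    temperature_k: float = 288.15
    ph: float = 5.0
    dw_fraction: float = 0.11

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _nearest_day(days: pd.Series, target: float) -> float:
    return float(days.iloc[(days - target).abs().argmin()])

def _mean_at(df: pd.DataFrame, treatment: str, analyte: str, day: float) -> float:
    sel = df[(df.treatment == treatment) & (df.analyte == analyte) & (df.day == day)]
    return float(sel.value.mean())


def _recovery_stage(df: pd.DataFrame, config: RunConfig) -> tuple[pd.DataFrame, list[str]]:
    rows = []
    warnings_log: list[str] = []
    for h2_tr, un_tr in config.pairings:
        days = df[df.treatment == h2_tr]["day"].drop_duplicates().sort_values()
        if days.empty:
            warnings_log.append(f"no data for treatment {h2_tr}")
            continue
        subresults = []
        for t1, t2 in config.periods:
            d1, d2 = _nearest_day(days, t1), _nearest_day(days, t2)
            inputs = recovery.RecoveryInputs(
                t1=d1, t2=d2,
                acetate_h=(_mean_at(df, h2_tr, "acetate", d1), _mean_at(df, h2_tr, "acetate", d2)),
                acetate_u=(_mean_at(df, un_tr, "acetate", d1), _mean_at(df, un_tr, "acetate", d2)),
                ch4_h=(_mean_at(df, h2_tr, "CH4", d1), _mean_at(df, h2_tr, "CH4", d2)),
                ch4_u=(_mean_at(df, un_tr, "CH4", d1), _mean_at(df, un_tr, "CH4", d2)),
                h2_h=(_mean_at(df, h2_tr, "H2", d1), _mean_at(df, h2_tr, "H2", d2)),
                h2_u=(_mean_at(df, un_tr, "H2", d1), _mean_at(df, un_tr, "H2", d2)),
            )
            res = recovery.recovery_result(inputs, h2_tr, config.denominator_floor)
            rows.append(res)
            if res.recovery_acetate is not None:
                subresults.append(res)
            else:
                warnings_log.append(
                    f"{h2_tr} {d1}-{d2}: recovery undefined (small denominator)"
                )
        if len(subresults) > 1:
            consumed = sum(r.consumed_h2 for r in subresults)
            rows.append(recovery.RecoveryResult(
                treatment=h2_tr,
                period=(subresults[0].period[0], subresults[-1].period[1]),
                consumed_h2=consumed,
                recovery_ch4=recovery.aggregate_recoveries(
                    [(r.recovery_ch4, r.consumed_h2) for r in subresults]),
                recovery_acetate=recovery.aggregate_recoveries(
                    [(r.recovery_acetate, r.consumed_h2) for r in subresults]),
                recovery_unknown=None,
                flags=frozenset(),
            ))
            last = rows[-1]
            rows[-1] = recovery.RecoveryResult(
                treatment=last.treatment, period=last.period,
                consumed_h2=last.consumed_h2,
                recovery_ch4=last.recovery_ch4,
                recovery_acetate=last.recovery_acetate,
                recovery_unknown=recovery.unknown_fraction(
                    last.recovery_acetate, last.recovery_ch4),
                flags=last.flags,
            )
    table = pd.DataFrame([
        {
            "treatment": r.treatment,
            "period": f"{r.period[0]:g}-{r.period[1]:g}",
            "consumed_h2_mm": r.consumed_h2,
            "pct_ch4": r.recovery_ch4,
            "pct_acetate": r.recovery_acetate,
            "pct_unknown": r.recovery_unknown,
            "flags": ";".join(sorted(f.value for f in r.flags)),
        }
        for r in rows
    ])
    return table, warnings_log


def _thermo_stage(
    df: pd.DataFrame, config: RunConfig, vessel: VesselSpec, constants
) -> pd.DataFrame:
    reactions = thermo.shipped_reactions(constants)
    rows = []
    wide = df.pivot_table(
        index=["treatment", "replicate", "day"], columns="analyte",
        values="value", aggfunc="first",
    )
    cens = df.pivot_table(
        index=["treatment", "replicate", "day"], columns="analyte",
        values="censored", aggfunc="first",
    )
    for key, conc_mm in wide.iterrows():
        treatment, replicate, day = key
        concs: dict[str, float | None] = {}
        for sp, gas in (("H2", True), ("CO2", True), ("CH4", True), ("acetate", False)):
            if sp not in conc_mm or math.isnan(conc_mm[sp]):
                concs[sp] = None
                continue
            if bool(cens.loc[key].get(sp, False)):
                concs[sp] = None
                continue
            amount_umol = conc_mm[sp] * vessel.liquid_volume_postsampling_ml
            if gas:
                c_aq, _ = chemistry.total_amount_to_dissolved(
                    amount_umol, sp, vessel,
                    ph=config.ph if sp == "CO2" else None, constants=constants,
                )
                concs[sp] = c_aq
            else:
                concs[sp] = conc_mm[sp] * 1e-3
        for name, rx in reactions.items():
            res = thermo.in_situ_delta_g(
                rx, concs, config.ph, config.temperature_k, constants
            )
            rows.append({
                "reaction": name, "treatment": treatment,
                "replicate": replicate, "day": day,
                "delta_g_kj": res.delta_g, "defined": res.defined,
                "classification": thermo.feasibility_classification(res).value,
            })
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle; returns the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    constants = (
        load_constants(config.constants_path)
        if config.constants_path else DEFAULT_CONSTANTS
    )
    vessel = VesselSpec(
        temperature_k=config.temperature_k, dw_fraction=config.dw_fraction
    )
    manifest: dict = {
        "fenflux_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "warnings": [],
        "outputs": {},
    }

    # --- chemistry ---------------------------------------------------------
    if config.measurements_path:
        meas = io.read_measurements(config.measurements_path)
    elif config.simulate_chemistry:
        scenario = simulate.ChemistryScenario(
            seed=config.seed,
            detection_limit_ppmv=config.detection_limit_ppmv,
            vessel=vessel,
        )
        meas, ledger = simulate.simulate_chemistry(scenario)
        manifest["chemistry_ledger"] = ledger
    else:
        raise ValueError("no measurement input: set measurements_path or simulate")
    meas = chemistry.censor_below_detection(
        meas, config.detection_limit_ppmv, "H2"
    ) if (meas["phase"] == "headspace_ppmv").any() else meas

    conc = (
        meas.groupby(["treatment", "day", "analyte"])["value"].mean().reset_index()
        .rename(columns={"value": "mm"})
    )
    factor = chemistry.dry_weight_factor(vessel)
    conc["umol_per_gdw"] = conc["mm"] * factor
    io.write_table(conc, outdir / "concentrations.tsv")
    manifest["outputs"]["concentrations"] = len(conc)
    manifest["dry_weight_factor"] = factor

    rates = {}
    for treatment in sorted(meas["treatment"].unique()):
        sel = meas[(meas.treatment == treatment) & (meas.analyte == "H2")]
        try:
            fit = chemistry.fit_linear_rate(sel)
        except chemistry.ChemistryInputError as exc:
            manifest["warnings"].append(f"H2 rate for {treatment}: {exc}")
            continue
        rates[treatment] = {
            "slope_mm_per_day": fit.slope_mm_per_day,
            "consumption_rate_mm_per_day": fit.consumption_rate,
            "r_squared": fit.r_squared,
            "n_days": fit.n_days,
        }
    (outdir / "rates.json").write_text(json.dumps(rates, indent=2))

    # --- recovery ----------------------------------------------------------
    rec_table, rec_warnings = _recovery_stage(meas, config)
    manifest["warnings"].extend(rec_warnings)
    io.write_table(rec_table, outdir / "recovery_raw.tsv")
    rounded = rec_table.copy()
    for col in ("consumed_h2_mm", "pct_ch4", "pct_acetate", "pct_unknown"):
        rounded[col] = rounded[col].map(
            lambda v: None if v is None or (isinstance(v, float) and math.isnan(v))
            else recovery.round_half_up(v, 1)
        )
    io.write_table(rounded, outdir / "recovery.tsv")
    manifest["outputs"]["recovery"] = len(rec_table)

    # --- thermodynamics ----------------------------------------------------
    dg = _thermo_stage(meas, config, vessel, constants)
    io.write_table(dg, outdir / "delta_g.tsv")
    manifest["outputs"]["delta_g"] = len(dg)
    n_undef = int((~dg["defined"]).sum()) if len(dg) else 0
    if n_undef:
        manifest["warnings"].append(f"{n_undef} dG rows undefined (censored inputs)")

    # --- community ---------------------------------------------------------
    table = None
    if config.counts_path and config.sample_meta_path:
        table = io.read_phylotype_table(
            config.counts_path, config.sample_meta_path, config.fasta_path
        )
    elif config.simulate_community:
        table, truth = simulate.simulate_community(
            simulate.CommunityScenario(seed=config.seed)
        )
        manifest["community_ground_truth"] = truth
    if table is not None:
        h2_tr, un_tr = config.pairings[0]
        stim = community.identify_stimulated(
            table, [h2_tr], [un_tr], markers=tuple(config.markers),
            seed=config.seed, n_boot=config.n_boot,
            p_max=config.p_max, lda_min=config.lda_min, ratio_min=config.ratio_min,
        )
        io.write_table(
            stim.reset_index(names="phylotype"), outdir / "stimulation.tsv"
        )
        manifest["outputs"]["stimulation"] = len(stim)
        manifest["outputs"]["stimulated_count"] = int(stim["stimulated"].sum())

        ra = table.relative_abundance()
        for marker in config.markers:
            samples = table.samples_for(marker, list(table.sample_meta["treatment"].unique()))
            if not samples:
                continue
            dist = community.bray_curtis(ra[samples].T)
            io.write_table(
                dist.reset_index(names="sample"),
                outdir / f"bray_curtis_{marker}.tsv",
            )
        if config.root_treatments:
            kept = community.root_abundance_screen(
                table, config.root_treatments,
                config.rrna_min_pct, config.gene_min_pct,
            )
            io.write_table(pd.DataFrame({"phylotype": kept}), outdir / "screen.tsv")
            manifest["outputs"]["screened"] = len(kept)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
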