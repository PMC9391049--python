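"""Synthetic microcosm chemistry and community tables.

The chemistry generator is a phenomenological, rate-ruled electron ledger —
not a mechanistic growth model.  It reproduces the two-stage fate of
supplemental H2 seen in anoxic peat incubations: consumed H2 first reduces an
unknown electron-acceptor pool (ferric iron / sulfate / humics surrogate,
yielding no carbon products), and once that pool is depleted the remaining
flow splits between hydrogenotrophic acetogenesis (4 H2 + 2 CO2 -> acetate)
and hydrogenotrophic methanogenesis (4 H2 + CO2 -> CH4).  Mass/electron
balance is exact on the noiseless ledger; multiplicative log-normal noise is
applied only to the emitted observations, and H2 observations below the
detection limit are emitted as censored records carrying the limit itself.

The community generator draws log-normal baseline compositions, multiplies
planted responders by a fold change in H2-supplemented samples of the chosen
marker types, adds per-sample log-normal dispersion, and realises counts as a
multinomial at fixed sequencing depth — so column sums equal the depth
exactly and the planted ground truth is returned alongside the table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemistry import VesselSpec, amount_to_concentration, headspace_to_total_amount
from .community import MARKERS, PhylotypeTable

DEFAULT_DAYS = (0.0, 2.0, 4.0, 7.0, 9.0, 11.0, 14.0, 17.0)


class ScenarioError(ValueError):
    pass


@dataclass(frozen=True)
class TreatmentSpec:
    name: str
    supplemental_h2: bool


@dataclass(frozen=True)
class ChemistryScenario:
    """Study-condition defaults: 10 mM supplemental H2 consumed at 0.45 mM/d
    over a 17-day schedule at 15 degC in the 27/10/9.5 ml vessel, n=3."""

    treatments: tuple[TreatmentSpec, ...] = (
        TreatmentSpec("SH", True), TreatmentSpec("SU", False),
    )
    initial_h2_mm: float = 10.0
    consumption_rate_mm_per_day: float = 0.45
    unknown_sink_pool_mm: float = 4.0       # H2-equivalents consumed first
    f_acetate: float = 0.7                  # H2 fraction to acetogenesis after pool
    f_ch4: float = 0.2                      # H2 fraction to methanogenesis after pool
    co2_initial_mm: float = 10.0
    co2_baseline_rate: float = 0.1          # respiration, both treatments (mM/d)
    acetate_baseline_rate: float = 0.02     # control-side background (mM/d)
    ch4_baseline_rate: float = 0.01
    fermentation_rates: tuple[tuple[str, float], ...] = ()
    noise_sd: float = 0.05                  # relative (log-normal sigma)
    detection_limit_ppmv: float = 10.0
    days: tuple[float, ...] = DEFAULT_DAYS
    n_replicates: int = 3
    ph: float = 5.0
    vessel: VesselSpec = field(default_factory=VesselSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.f_acetate < 0 or self.f_ch4 < 0 or self.f_acetate + self.f_ch4 > 1:
            raise ScenarioError("need f_acetate, f_ch4 >= 0 and f_acetate + f_ch4 <= 1")
        if self.unknown_sink_pool_mm < 0 or self.consumption_rate_mm_per_day < 0:
            raise ScenarioError("pool and rates must be nonnegative")
        if len(self.days) < 2 or any(
            b <= a for a, b in zip(self.days, self.days[1:])
        ) or self.days[0] < 0:
            raise ScenarioError("days must be strictly increasing and nonnegative")


def detection_limit_mm(scenario: ChemistryScenario) -> float:
    """The H2 detection limit expressed on the liquid-mM total-amount scale."""
    amount = headspace_to_total_amount(
        scenario.detection_limit_ppmv, "H2", scenario.vessel
    )
    return amount_to_concentration(amount.total_umol, scenario.vessel)


def _true_concentrations(
    scenario: ChemistryScenario, treatment: TreatmentSpec, day: float
) -> dict[str, float]:
    if treatment.supplemental_h2:
        h2 = max(scenario.initial_h2_mm - scenario.consumption_rate_mm_per_day * day, 0.0)
        consumed = scenario.initial_h2_mm - h2
    else:
        h2 = 0.0
        consumed = 0.0
    to_pool = min(consumed, scenario.unknown_sink_pool_mm)
    to_products = consumed - to_pool
    acetate_h2 = scenario.f_acetate * to_products / 4.0
    ch4_h2 = scenario.f_ch4 * to_products / 4.0
    conc = {
        "H2": h2,
        "acetate": acetate_h2 + scenario.acetate_baseline_rate * day,
        "CH4": ch4_h2 + scenario.ch4_baseline_rate * day,
        "CO2": (
            scenario.co2_initial_mm + scenario.co2_baseline_rate * day
            - 2.0 * acetate_h2 - ch4_h2
        ),
    }
    for analyte, rate in scenario.fermentation_rates:
        conc[analyte] = conc.get(analyte, 0.0) + rate * day
    return conc


def ledger(scenario: ChemistryScenario) -> dict[str, dict[str, float]]:
    """Noiseless electron bookkeeping per treatment over the full schedule."""
    out: dict[str, dict[str, float]] = {}
    t_end = scenario.days[-1]
    for tr in scenario.treatments:
        if tr.supplemental_h2:
            h2_end = max(
                scenario.initial_h2_mm - scenario.consumption_rate_mm_per_day * t_end,
                0.0,
            )
            consumed = scenario.initial_h2_mm - h2_end
        else:
            consumed = 0.0
        to_pool = min(consumed, scenario.unknown_sink_pool_mm)
        to_products = consumed - to_pool
        acetate = scenario.f_acetate * to_products / 4.0
        ch4 = scenario.f_ch4 * to_products / 4.0
        unknown_h2 = to_pool + (1.0 - scenario.f_acetate - scenario.f_ch4) * to_products
        out[tr.name] = {
            "dosed_h2_mm": scenario.initial_h2_mm if tr.supplemental_h2 else 0.0,
            "consumed_h2_mm": consumed,
            "h2_to_pool_mm": to_pool,
            "h2_to_acetate_mm": scenario.f_acetate * to_products,
            "h2_to_ch4_mm": scenario.f_ch4 * to_products,
            "acetate_formed_mm": acetate,
            "ch4_formed_mm": ch4,
            "electrons_consumed": 2.0 * consumed,
            "electrons_acetate": 8.0 * acetate,
            "electrons_ch4": 8.0 * ch4,
            "electrons_unknown": 2.0 * unknown_h2,
        }
    return out


def simulate_chemistry(
    scenario: ChemistryScenario,
) -> tuple[pd.DataFrame, dict[str, dict[str, float]]]:
    """Generate a tidy measurement table plus the ground-truth ledger.

    Identical seeds give identical tables; noise never touches the ledger.
    """
    rng = np.random.default_rng(scenario.seed)
    limit_mm = detection_limit_mm(scenario)
    rows = []
    for tr in scenario.treatments:
        for rep in range(1, scenario.n_replicates + 1):
            for day in scenario.days:
                truth = _true_concentrations(scenario, tr, day)
                for analyte in sorted(truth):
                    true_val = truth[analyte]
                    if scenario.noise_sd > 0:
                        obs = true_val * rng.lognormal(0.0, scenario.noise_sd)
                    else:
                        obs = true_val
                    censored = False
                    if analyte == "H2" and obs < limit_mm:
                        obs = limit_mm
                        censored = True
                    rows.append(
                        (tr.name, rep, day, analyte, "liquid_mM", obs, censored)
                    )
    df = pd.DataFrame(
        rows,
        columns=["treatment", "replicate", "day", "analyte", "phase", "value",
                 "censored"],
    )
    ph = pd.DataFrame(
        [
            (tr.name, rep, day, scenario.ph)
            for tr in scenario.treatments
            for rep in range(1, scenario.n_replicates + 1)
            for day in scenario.days
        ],
        columns=["treatment", "replicate", "day", "ph"],
    )
    df.attrs["ph_records"] = ph
    return df, ledger(scenario)


# ---------------------------------------------------------------------------
# Community tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Responder:
    """A planted H2-responsive feature.

    ``base_abundance`` pins the spike's baseline scale (1.0 = the median of
    the log-normal baseline), the usual design for a spike-in benchmark: the
    discriminant effect size is absolute-abundance-dependent, so leaving the
    spike's baseline to the random draw would measure the rarity lottery as
    much as the procedure.  ``None`` keeps the drawn baseline.
    """

    feature: int                    # index into the feature list
    fold_change: float
    markers: tuple[str, ...] = MARKERS
    base_abundance: float | None = None

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ScenarioError("fold_change must be positive")
        if self.base_abundance is not None and self.base_abundance <= 0:
            raise ScenarioError("base_abundance must be positive")


@dataclass(frozen=True)
class CommunityScenario:
    n_features: int = 150
    n_replicates: int = 3
    h2_treatment: str = "SH"
    unsupp_treatment: str = "SU"
    markers: tuple[str, ...] = MARKERS
    baseline_sigma: float = 2.0     # log-normal sigma of the base composition
    dispersion: float = 0.5         # per-sample log-normal replicate wiggle
    sequencing_depth: int = 50_000
    responders: tuple[Responder, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sequencing_depth <= 0 or self.n_features <= 0:
            raise ScenarioError("depth and n_features must be positive")
        for r in self.responders:
            if not (0 <= r.feature < self.n_features):
                raise ScenarioError(f"responder feature {r.feature} out of range")


def simulate_community(
    scenario: CommunityScenario,
) -> tuple[PhylotypeTable, dict]:
    """Generate a phylotype count table with planted H2 responders.

    Returns the table plus a ground-truth dict listing the planted responder
    feature ids and the scenario seed.
    """
    rng = np.random.default_rng(scenario.seed)
    base = rng.lognormal(0.0, scenario.baseline_sigma, scenario.n_features)
    for r in scenario.responders:
        if r.base_abundance is not None:
            base[r.feature] = r.base_abundance
    feature_ids = [f"PT{i:04d}" for i in range(scenario.n_features)]
    fold = {
        m: np.ones(scenario.n_features) for m in scenario.markers
    }
    for r in scenario.responders:
        for m in r.markers:
            if m in fold:
                fold[m][r.feature] = r.fold_change

    if scenario.sequencing_depth * (base.max() / base.sum()) < 1.0:
        warnings.warn(
            "sequencing depth too small to realise the baseline "
            "(expected count < 1 for every feature)",
            stacklevel=2,
        )

    counts: dict[str, np.ndarray] = {}
    meta_rows = []
    for marker in scenario.markers:
        for treatment in (scenario.unsupp_treatment, scenario.h2_treatment):
            is_h2 = treatment == scenario.h2_treatment
            for rep in range(1, scenario.n_replicates + 1):
                expected = base * rng.lognormal(
                    0.0, scenario.dispersion, scenario.n_features
                )
                if is_h2:
                    expected = expected * fold[marker]
                p = expected / expected.sum()
                sample_id = f"{treatment}{rep}_{marker}"
                counts[sample_id] = rng.multinomial(scenario.sequencing_depth, p)
                meta_rows.append((sample_id, marker, treatment, rep))

    counts_df = pd.DataFrame(counts, index=feature_ids)
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "marker", "treatment", "replicate"]
    ).set_index("sample_id")
    table = PhylotypeTable(counts=counts_df, sample_meta=meta)
    truth = {
        "responders": [
            {"feature": feature_ids[r.feature], "fold_change": r.fold_change,
             "markers": list(r.markers)}
            for r in scenario.responders
        ],
        "seed": scenario.seed,
    }
    return table, truth


def toy_representative_sequences(
    feature_ids: list[str], length: int = 250, seed: int = 0
) -> dict[str, str]:
    """Deterministic random DNA sequences for sequence-matching tests."""
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGT"))
    return {
        fid: "".join(rng.choice(alphabet, size=length))
        for fid in feature_ids
    }
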