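"""Synthetic deep-lake bacterioplankton survey generator with ground truth.

Emulates a one-year monthly profile survey of a dimictic, seasonally
ice-covered high-mountain lake: ~14 four-weekly sampling dates at five
depths (2, 10, 20, 35, 60 m), with ice and snow cover for roughly half the
year.  Each sample belongs to one of six latent habitat states derived
deterministically from its date, depth and ice flag:

* ``under_ice`` — the ice-covered bulk water column;
* ``thaw_hypolimnion`` — the thaw period plus the stratified-summer deep
  layers;
* ``early_stratification`` — first stratified dates, upper depths;
* ``epilimnion`` — mid/late-summer upper depths;
* ``overturn`` — autumn mixing and the first weeks of new ice;
* ``deep_layer`` — the deepest horizon in late winter (hypoxic, sediment
  influenced).

Taxa are planted as archetypes.  *Resistant* taxa have the same expected
relative abundance everywhere.  *Ice-on resilient* taxa each favor one
ice-associated state (under-ice, thaw or overturn); *ice-off resilient*
taxa favor one epilimnetic state (early stratification or epilimnion);
*deep* specialists favor the deep-layer state.  A favored state multiplies
the taxon's baseline relative abundance by ``effect_size``.  *Sporadic*
taxa appear in only 2–5 random samples at low abundance.  Counts are
Dirichlet-multinomial (overdispersed multinomial) draws at log-normal
library sizes; at the default moderate sequencing depth a 4-fold effect
also produces realistic presence/absence patchiness for rarer taxa, which
is what lets fidelity anchor fine-grained partitions.  The environmental
table draws each chemistry variable from state-specific Gaussian means so
the discriminant analysis has signal.  Everything is a deterministic
function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .otu_io import OtuTable

STATE_NAMES = (
    "under_ice",
    "thaw_hypolimnion",
    "early_stratification",
    "epilimnion",
    "overturn",
    "deep_layer",
)

ARCHETYPES = ("resistant", "ice_on", "ice_off", "deep", "sporadic")

#: primary favored states cycled through by each archetype's taxa
PRIMARY_POOL = {
    "ice_on": ("under_ice", "thaw_hypolimnion", "overturn"),
    "ice_off": ("early_stratification", "epilimnion"),
    "deep": ("deep_layer",),
}

EPILIMNETIC = ("early_stratification", "epilimnion")


@dataclass
class SyntheticConfig:
    """Study-design and noise parameters for the generator.

    Defaults reproduce the survey geometry the analysis assumes: 14
    four-weekly dates x 5 depths = 70 samples, ice cover December–May,
    six latent states with unequal sizes (31/13/6/6/10/4), 200 taxa
    (60 resistant, 60 ice-on, 40 ice-off, 20 deep specialists, 20
    sporadic), a 4-fold favored-state effect and moderate count
    overdispersion.
    """

    n_dates: int = 14
    depths_m: tuple[float, ...] = (2.0, 10.0, 20.0, 35.0, 60.0)
    start_date: date = date(2013, 1, 7)
    interval_days: int = 28
    ice_months: tuple[int, ...] = (12, 1, 2, 3, 4, 5)
    n_states: int = 6
    n_resistant: int = 60
    n_ice_on: int = 60
    n_ice_off: int = 40
    n_deep: int = 20
    n_sporadic: int = 20
    effect_size: float = 4.0
    #: Dirichlet-multinomial overdispersion; concentration = 1/dispersion
    dispersion: float = 5e-4
    library_size_mean: float = 2000.0
    library_size_sigma: float = 0.2  # sigma of log library size
    baseline_sigma: float = 1.0  # sigma of the log-normal taxon baseline
    sporadic_scale: float = 0.3  # baseline multiplier for sporadic taxa
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dates < 1 or not self.depths_m:
            raise ValueError("need at least one date and one depth")
        if self.effect_size < 1:
            raise ValueError("effect_size must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if min(self.n_resistant, self.n_ice_on, self.n_ice_off,
               self.n_deep, self.n_sporadic) < 0:
            raise ValueError("archetype counts must be >= 0")
        if self.n_states != len(STATE_NAMES):
            raise ValueError(
                f"the built-in habitat template defines {len(STATE_NAMES)} states; "
                "other n_states require a user-supplied state mapping"
            )

    @property
    def n_taxa(self) -> int:
        return (self.n_resistant + self.n_ice_on + self.n_ice_off
                + self.n_deep + self.n_sporadic)


def _state_for(month: int, depth: float, ice: bool) -> str:
    """Deterministic habitat-template lookup for one sample."""
    if ice:
        if depth >= 60 and month in (3, 4, 5):
            return "deep_layer"  # late-winter hypoxic deep horizon
        if month in (11, 12):
            return "overturn"  # early ice still mixes with autumn water
        return "under_ice"
    if month == 6:
        return "thaw_hypolimnion"  # thaw / spring mixing
    if month == 11:
        return "overturn"
    if depth >= 35:
        return "thaw_hypolimnion"  # stratified-summer hypolimnion
    if month in (7, 8):
        return "early_stratification"
    return "epilimnion"


def assign_states(config: SyntheticConfig) -> pd.DataFrame:
    """Build the sampling design and its latent habitat states.

    Returns one row per sample with ``sample_id, date, depth_m, ice_cover,
    state`` — a deterministic function of the configuration (no randomness).
    """
    rows = []
    for i in range(config.n_dates):
        d = config.start_date + timedelta(days=i * config.interval_days)
        ice = d.month in config.ice_months
        for depth in config.depths_m:
            rows.append(
                {
                    "sample_id": f"S{d:%Y%m%d}_{int(depth):02d}m",
                    "date": pd.Timestamp(d),
                    "depth_m": float(depth),
                    "ice_cover": ice,
                    "state": _state_for(d.month, depth, ice),
                }
            )
    return pd.DataFrame(rows)


def _taxon_truth(config: SyntheticConfig) -> pd.DataFrame:
    rows = []
    idx = 0

    def add(archetype: str, count: int) -> None:
        nonlocal idx
        pool = PRIMARY_POOL.get(archetype, ())
        for j in range(count):
            favored = pool[j % len(pool)] if pool else (
                "all" if archetype == "resistant" else ""
            )
            rows.append(
                {"taxon_id": f"OTU_{idx + 1:04d}", "archetype": archetype,
                 "favored_state": favored}
            )
            idx += 1

    add("resistant", config.n_resistant)
    add("ice_on", config.n_ice_on)
    add("ice_off", config.n_ice_off)
    add("deep", config.n_deep)
    add("sporadic", config.n_sporadic)
    return pd.DataFrame(rows)


def _expected_multipliers(
    truth: pd.DataFrame, states: np.ndarray, config: SyntheticConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-taxon, per-sample fold-change applied to the baseline abundance."""
    n_taxa, n_samples = len(truth), states.size
    M = np.ones((n_taxa, n_samples))
    for i, row in truth.iterrows():
        arch, fav = row["archetype"], row["favored_state"]
        if arch == "resistant":
            continue
        if arch == "sporadic":
            n_present = int(rng.integers(2, 6))
            present = rng.choice(n_samples, size=n_present, replace=False)
            M[i] = 0.0
            M[i, present] = 1.0
            continue
        M[i, states == fav] = config.effect_size
    return M


# per-state environmental means: (temperature, O2, Chla, pH, NO3, NO2, NH4,
# SRP, DOP, DON, DRSi, SO4, DOC, CO2, PC, PN, PP); units follow the raw
# env table conventions (umol/L nutrients, mg/L O2/DOC, ug/L Chla, deg C).
_ENV_MEANS = {
    #                 T     O2   Chla   pH   NO3   NO2   NH4    SRP     DOP    DON  DRSi  SO4  DOC   CO2   PC   PN    PP
    "under_ice":            (2.0, 9.0, 0.20, 6.4, 8.0, 0.05, 0.30, 0.008, 0.012, 8.0, 20.0, 28.0, 0.35, 30.0, 8.0, 1.0, 0.035),
    "thaw_hypolimnion":     (4.0, 9.5, 0.80, 6.6, 10.0, 0.12, 0.40, 0.010, 0.015, 9.0, 16.0, 27.0, 0.40, 22.0, 10.0, 1.4, 0.045),
    "early_stratification": (9.0, 9.2, 1.00, 6.9, 9.0, 0.10, 0.25, 0.006, 0.012, 8.0, 12.0, 27.0, 0.45, 15.0, 12.0, 1.6, 0.030),
    "epilimnion":           (12.5, 8.8, 1.50, 7.1, 6.0, 0.06, 0.20, 0.005, 0.010, 7.0, 10.0, 26.0, 0.50, 10.0, 14.0, 1.8, 0.025),
    "overturn":             (5.0, 9.3, 0.90, 6.6, 9.0, 0.10, 0.35, 0.009, 0.013, 8.5, 15.0, 27.0, 0.40, 20.0, 10.0, 1.3, 0.040),
    "deep_layer":           (3.5, 3.0, 0.10, 6.1, 10.0, 0.08, 2.50, 0.012, 0.018, 9.0, 30.0, 30.0, 0.30, 60.0, 7.0, 0.9, 0.040),
}
_ENV_VARS = ("temperature", "O2", "Chla", "pH", "NO3", "NO2", "NH4",
             "SRP", "DOP", "DON", "DRSi", "SO4", "DOC", "CO2", "PC", "PN", "PP")
_ENV_CV = 0.12  # relative sd for multiplicative noise
_ADDITIVE = {"temperature": 0.6, "pH": 0.08}  # absolute sd instead


def _generate_env(
    samples: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    states = samples["state"].to_numpy()
    n = len(samples)
    data: dict[str, np.ndarray] = {}
    means = np.array([_ENV_MEANS[s] for s in states])
    for j, var in enumerate(_ENV_VARS):
        mu = means[:, j]
        if var in _ADDITIVE:
            vals = mu + rng.normal(0.0, _ADDITIVE[var], size=n)
        else:
            vals = mu * (1.0 + _ENV_CV * rng.normal(size=n))
            vals = np.clip(vals, 0.05 * mu, None)
        data[var] = vals
    # totals by construction, so DON/DOP recovered by difference are exact
    din = data["NO3"] + data["NO2"] + data["NH4"]
    data["TN"] = din + data.pop("DON")
    data["TDP"] = data["SRP"] + data.pop("DOP")
    # per-date Secchi depth, shared across the profile
    z_by_date = {
        d: float(np.clip(rng.normal(8.0, 1.0), 4.0, None))
        for d in pd.unique(samples["date"])
    }
    data["z_sd"] = samples["date"].map(z_by_date).to_numpy()
    env = pd.DataFrame({"sample_id": samples["sample_id"].to_numpy(), **data})
    env["depth_m"] = samples["depth_m"].to_numpy()
    return env


def generate_community(
    config: SyntheticConfig | None = None, seed: int | None = None
) -> tuple[OtuTable, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw one synthetic survey.

    Returns ``(otu_table, sample_frame, env_frame, taxon_truth)``.  The
    sample frame carries the latent state as ``truth_label``; the taxon
    truth table records each taxon's archetype and primary favored state.
    """
    config = config or SyntheticConfig()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    samples = assign_states(config)
    truth = _taxon_truth(config)
    states = samples["state"].to_numpy()
    n_taxa, n_samples = config.n_taxa, len(samples)
    if n_taxa == 0:
        raise ValueError("configuration generates no taxa")

    baseline = rng.lognormal(mean=0.0, sigma=config.baseline_sigma, size=n_taxa)
    baseline[truth["archetype"].to_numpy() == "sporadic"] *= config.sporadic_scale
    M = _expected_multipliers(truth, states, config, rng)
    expected = baseline[:, None] * M
    probs = expected / expected.sum(axis=0, keepdims=True)

    sizes = np.maximum(
        rng.lognormal(np.log(config.library_size_mean), config.library_size_sigma,
                      size=n_samples),
        1.0,
    ).astype(np.int64)

    counts = np.empty((n_taxa, n_samples), dtype=np.int64)
    for j in range(n_samples):
        p = probs[:, j]
        if config.dispersion > 0:
            alpha = p / config.dispersion
            g = rng.gamma(np.where(alpha > 0, alpha, 1e-12)) * (alpha > 0)
            tot = g.sum()
            p = g / tot if tot > 0 else p
        counts[:, j] = rng.multinomial(sizes[j], p)

    table = OtuTable(
        counts=counts,
        taxon_ids=list(truth["taxon_id"]),
        sample_ids=list(samples["sample_id"]),
        taxonomy=[f"Bacteria;synthetic_{a}" for a in truth["archetype"]],
    )
    sample_frame = samples.rename(columns={"state": "truth_label"})
    env = _generate_env(samples, rng)
    return table, sample_frame, env, truth
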