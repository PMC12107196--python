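"""Synthetic ED presentation registry.

Real presentation-level emergency-department data with admission outcomes are
not shareable, so this module generates a registry with the statistical
structure the downstream analysis assumes:

* a universe of ICD-10 diagnosis codes with Zipf-like presentation
  frequencies and a latent multi-tier admission-risk structure (each code's
  baseline admission probability is drawn from a Beta distribution centred on
  its tier's risk level);
* presentation-level covariates (demographics, vital signs, comorbidity
  score, prior-encounter counts) drawn from distributions calibrated to the
  marginal prevalences of an ambulatory tertiary-ED case mix;
* an admission outcome whose logit is the code's baseline risk plus
  configured covariate effects, so both the clustering stage (marginal
  per-code risk) and the regression stage (covariate odds ratios) have a
  recoverable ground truth.

All randomness flows from the single ``SimulationConfig.seed`` through named
:func:`numpy.random.default_rng` streams; regenerating with the same
configuration is bit-identical.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import truncnorm

from ._util import ConfigurationError, RegistryParseError

__all__ = [
    "SimulationConfig",
    "CodeUniverse",
    "DEFAULT_COVARIATE_EFFECTS",
    "REGISTRY_COLUMNS",
    "generate_code_universe",
    "generate_presentations",
    "write_registry",
    "read_registry",
    "build_features",
]

#: Registry file schema, in column order.
REGISTRY_COLUMNS = [
    "id", "icd10", "admitted", "age", "sex", "ethnicity",
    "sbp", "pulse", "temp", "cci",
    "prior_ed", "prior_inpt", "prior_surg", "prior_icu",
    "prior_hd", "prior_ica", "prior_infect",
]

_CODE_RE = re.compile(r"^[A-Z][0-9]{2}[0-9A-Z]?$")

#: Default presentation-level effects on the admission log-odds, expressed as
#: log odds ratios. Magnitudes follow the associations reported for
#: ambulatory ED cohorts: comorbidity burden (Charlson mild/moderate/severe),
#: abnormal vitals (tachycardia, hyperthermia) and recent utilisation.
DEFAULT_COVARIATE_EFFECTS: dict[str, float] = {
    "cci_mild": math.log(2.55),
    "cci_moderate": math.log(3.50),
    "cci_severe": math.log(5.28),
    "tachycardia": math.log(1.46),
    "hyperthermia": math.log(2.32),
    "prior_surg": math.log(1.31),
    "prior_inpt": math.log(1.16),
    "prior_ed": math.log(0.86),
    "prior_icu": math.log(0.85),
    "prior_hd": math.log(0.85),
}


_DEFAULT_TIER_SHARES = (0.61, 0.206, 0.129, 0.055)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic registry.

    Defaults encode the study conditions the generator emulates: ~510 codes
    over four risk tiers whose centres match the admission rates of a
    four-cluster ambulatory ED stratification (4.7%, 19.5%, 47.8%, 78%), tier
    sizes proportional to the reported per-cluster code counts, Zipf exponent
    1 for code frequencies with per-tier presentation shares of
    61/20.6/12.9/5.5% (so the expected marginal admission rate is the
    share-weighted 17.3%), and covariate effects at the reported OR
    magnitudes.
    """

    n_presentations: int = 200_000
    n_codes: int = 510
    n_tiers: int = 4
    tier_risk_centers: tuple[float, ...] = (0.047, 0.195, 0.478, 0.78)
    tier_proportions: tuple[float, ...] = (262 / 510, 104 / 510, 66 / 510, 78 / 510)
    tier_presentation_shares: tuple[float, ...] | None = (0.61, 0.206, 0.129, 0.055)
    tier_risk_spread: float = 200.0
    zipf_exponent: float = 1.0
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    code_extension_prob: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        centers = tuple(self.tier_risk_centers)
        if len(centers) != self.n_tiers:
            raise ConfigurationError(
                f"n_tiers={self.n_tiers} but {len(centers)} tier_risk_centers given"
            )
        if any(not (0.0 < c < 1.0) for c in centers):
            raise ConfigurationError("tier_risk_centers must lie strictly in (0, 1)")
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise ConfigurationError("tier_risk_centers must be strictly increasing")
        if self.zipf_exponent <= 0:
            raise ConfigurationError("zipf_exponent must be positive")
        if self.tier_risk_spread <= 0:
            raise ConfigurationError("tier_risk_spread must be positive")
        props = tuple(self.tier_proportions)
        if len(props) != self.n_tiers or any(p <= 0 for p in props):
            raise ConfigurationError("tier_proportions must be positive, one per tier")
        shares = self.tier_presentation_shares
        if shares is not None and len(shares) != self.n_tiers:
            if tuple(shares) == _DEFAULT_TIER_SHARES:
                # default 4-tier calibration does not apply; plain Zipf weights
                object.__setattr__(self, "tier_presentation_shares", None)
            else:
                raise ConfigurationError(
                    "tier_presentation_shares must have one entry per tier")
        elif shares is not None and any(s <= 0 for s in shares):
            raise ConfigurationError("tier_presentation_shares must be positive")
        if self.n_presentations < 0 or self.n_codes < 1:
            raise ConfigurationError("n_presentations >= 0 and n_codes >= 1 required")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class CodeUniverse:
    """The latent code-level truth: risks, tiers and sampling weights."""

    codes: tuple[str, ...]
    true_risk: np.ndarray
    tier: np.ndarray
    frequency_weight: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.codes)
        if len(set(self.codes)) != n:
            raise ConfigurationError("code strings must be unique")
        if self.true_risk.shape != (n,) or np.any((self.true_risk < 0) | (self.true_risk > 1)):
            raise ConfigurationError("true_risk must be per-code probabilities in [0, 1]")
        if self.frequency_weight.shape != (n,) or np.any(self.frequency_weight <= 0):
            raise ConfigurationError("frequency weights must be positive, one per code")
        w = self.frequency_weight
        if not math.isclose(float(w.sum()), 1.0, rel_tol=1e-9):
            object.__setattr__(self, "frequency_weight", w / w.sum())

    def __len__(self) -> int:
        return len(self.codes)


def _candidate_prefixes() -> list[str]:
    """Three-character ICD-10 prefixes eligible as primary ED diagnoses.

    Drawn from the packaged WHO block table, excluding the external-cause
    chapter (V-Y), whose codes are not primary diagnoses.
    """
    from .blocks import expand_block_range, parse_block_table

    prefixes: list[str] = []
    for block in parse_block_table():
        if block.block_id[0] in "VWXY":
            continue
        prefixes.extend(expand_block_range(block.block_id))
    return prefixes


def _tier_counts(n_codes: int, proportions: tuple[float, ...]) -> np.ndarray:
    """Largest-remainder apportionment of codes over tiers."""
    p = np.asarray(proportions, dtype=float)
    p = p / p.sum()
    raw = p * n_codes
    counts = np.floor(raw).astype(int)
    short = n_codes - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:short]] += 1
    return counts


def generate_code_universe(config: SimulationConfig) -> CodeUniverse:
    """Draw the ICD-10 code universe: codes, tiers, risks and Zipf weights.

    Each code is assigned a latent tier (sizes follow
    ``config.tier_proportions``), a baseline admission risk drawn from
    Beta(c*s, (1-c)*s) with c its tier's centre and s the spread
    (``tier_risk_spread=inf`` degenerates to risk exactly c), and a sampling
    weight proportional to rank^(-zipf_exponent) with ranks randomly
    permuted over codes.
    """
    rng = np.random.default_rng([config.seed, 1])

    pool = _candidate_prefixes()
    if config.n_codes > len(pool):
        raise ConfigurationError(
            f"n_codes={config.n_codes} exceeds the {len(pool)} eligible prefixes"
        )
    chosen = rng.choice(len(pool), size=config.n_codes, replace=False)
    extend = rng.random(config.n_codes) < config.code_extension_prob
    digits = rng.integers(0, 10, size=config.n_codes)
    codes = tuple(
        pool[i] + (str(d) if e else "")
        for i, e, d in zip(chosen, extend, digits)
    )

    counts = _tier_counts(config.n_codes, tuple(config.tier_proportions))
    tier = np.repeat(np.arange(1, config.n_tiers + 1), counts)
    tier = rng.permutation(tier)

    centers = np.asarray(config.tier_risk_centers)[tier - 1]
    if math.isinf(config.tier_risk_spread):
        risk = centers.copy()
    else:
        s = config.tier_risk_spread
        risk = rng.beta(centers * s, (1.0 - centers) * s)

    ranks = rng.permutation(config.n_codes) + 1
    weight = ranks.astype(float) ** (-config.zipf_exponent)
    weight /= weight.sum()
    if config.tier_presentation_shares is not None:
        # rescale so each tier's total sampling weight equals its target
        # presentation share: in the cohort this emulates, low-risk codes are
        # disproportionately frequent, which is what pins the marginal
        # admission rate at the share-weighted mean of the tier centres
        shares = np.asarray(config.tier_presentation_shares, dtype=float)
        shares = shares / shares.sum()
        for t in range(1, config.n_tiers + 1):
            mask = tier == t
            if mask.any():
                weight[mask] *= shares[t - 1] / weight[mask].sum()
        weight /= weight.sum()

    return CodeUniverse(codes=codes, true_risk=risk, tier=tier, frequency_weight=weight)


# Covariate sampling distributions, calibrated so categorical prevalences
# match an ambulatory ED case mix (hypotension 0.1%/hypertension 41.4%,
# bradycardia 3.6%/tachycardia 26.7%, hypothermia 2%/hyperthermia 8.1%,
# CCI none/mild/moderate/severe = 81.9/11/3.8/3.4%).
_AGE_MEAN, _AGE_SD, _AGE_LO, _AGE_HI = 46.2, 19.4, 0.0, 110.0
_SBP_MEAN, _SBP_SD = 127.4, 12.1
_PULSE_MEAN, _PULSE_SD = 82.3, 12.4
_TEMP_MEAN, _TEMP_SD = 36.69, 0.58
_SEX_LEVELS, _SEX_P = ["female", "male"], [0.466, 0.534]
_ETH_LEVELS, _ETH_P = ["Chinese", "Indian", "Malay", "Others"], [0.584, 0.155, 0.122, 0.139]
_CCI_VALUES = np.arange(8)
_CCI_P = np.array([0.819, 0.070, 0.040, 0.025, 0.013, 0.019, 0.009, 0.005])
_PRIOR_MEANS = {
    "prior_ed": 0.6, "prior_inpt": 0.2, "prior_surg": 0.05,
    "prior_icu": 0.01, "prior_hd": 0.02, "prior_ica": 0.01,
    "prior_infect": 0.08,
}


def build_features(df: pd.DataFrame, names) -> pd.DataFrame:
    """Derive the named model features from raw registry columns.

    Indicator features use the standard vital-sign and Charlson cutoffs;
    count features pass through per unit.
    """
    out = {}
    for name in names:
        if name == "tachycardia":
            out[name] = (df["pulse"] > 90).astype(float)
        elif name == "bradycardia":
            out[name] = (df["pulse"] < 60).astype(float)
        elif name == "hyperthermia":
            out[name] = (df["temp"] > 37.5).astype(float)
        elif name == "hypothermia":
            out[name] = (df["temp"] < 35.5).astype(float)
        elif name == "hypertension":
            out[name] = (df["sbp"] > 130).astype(float)
        elif name == "hypotension":
            out[name] = (df["sbp"] < 90).astype(float)
        elif name == "cci_mild":
            out[name] = df["cci"].between(1, 2).astype(float)
        elif name == "cci_moderate":
            out[name] = df["cci"].between(3, 4).astype(float)
        elif name == "cci_severe":
            out[name] = (df["cci"] >= 5).astype(float)
        elif name == "male":
            out[name] = (df["sex"] == "male").astype(float)
        elif name in df.columns and pd.api.types.is_numeric_dtype(df[name]):
            out[name] = df[name].astype(float)
        else:
            raise ConfigurationError(f"unknown covariate feature: {name!r}")
    return pd.DataFrame(out, index=df.index)


def generate_presentations(universe: CodeUniverse, config: SimulationConfig) -> pd.DataFrame:
    """Simulate presentation records from a code universe.

    Admission is Bernoulli with
    ``logit(p) = logit(true_risk[code]) + sum_f effect_f * (x_f - mean(x_f))``;
    features are centred at their sample means so each code's marginal
    admission rate stays at its nominal baseline risk.
    """
    if len(universe) == 0:
        raise ConfigurationError("empty code universe")
    n = config.n_presentations
    rng = np.random.default_rng([config.seed, 2])

    idx = rng.choice(len(universe), size=n, p=universe.frequency_weight)

    a = (_AGE_LO - _AGE_MEAN) / _AGE_SD
    b = (_AGE_HI - _AGE_MEAN) / _AGE_SD
    age = np.round(truncnorm.rvs(a, b, loc=_AGE_MEAN, scale=_AGE_SD, size=n, random_state=rng), 1)
    sex = rng.choice(_SEX_LEVELS, size=n, p=_SEX_P)
    ethnicity = rng.choice(_ETH_LEVELS, size=n, p=_ETH_P)
    sbp = np.clip(np.round(rng.normal(_SBP_MEAN, _SBP_SD, size=n)), 50, 250).astype(int)
    pulse = np.clip(np.round(rng.normal(_PULSE_MEAN, _PULSE_SD, size=n)), 30, 220).astype(int)
    temp = np.clip(np.round(rng.normal(_TEMP_MEAN, _TEMP_SD, size=n), 1), 33.0, 42.0)
    cci = rng.choice(_CCI_VALUES, size=n, p=_CCI_P / _CCI_P.sum())
    priors = {k: rng.poisson(mu, size=n) for k, mu in _PRIOR_MEANS.items()}

    df = pd.DataFrame({
        "id": [f"P{i:07d}" for i in range(n)],
        "icd10": [universe.codes[i] for i in idx],
        "admitted": 0,
        "age": age, "sex": sex, "ethnicity": ethnicity,
        "sbp": sbp, "pulse": pulse, "temp": temp, "cci": cci,
        **priors,
    })[REGISTRY_COLUMNS]

    eps = 1e-9
    lin = logit(np.clip(universe.true_risk[idx], eps, 1 - eps))
    effects = config.covariate_effects or {}
    if effects and n > 0:
        feats = build_features(df, effects.keys())
        centred = feats - feats.mean(axis=0)
        coef = np.array([effects[c] for c in feats.columns])
        lin = lin + centred.to_numpy() @ coef
    df["admitted"] = (rng.random(n) < expit(lin)).astype(int)
    return df


def write_registry(records: pd.DataFrame, path) -> None:
    """Write a registry file (comma-delimited, header row, empty = missing)."""
    records.to_csv(path, index=False)


def read_registry(path) -> pd.DataFrame:
    """Read and validate a registry file.

    Codes are whitespace-stripped and upper-cased. A malformed cell (bad code
    pattern, non-numeric vital, admitted outside {0, 1}) raises
    :class:`RegistryParseError` naming the row and column; missing icd10 or
    admitted values are tolerated here and resolved by
    :func:`edrisk.preprocess.impute_missing`.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in REGISTRY_COLUMNS if c not in df.columns]
    if missing_cols:
        raise RegistryParseError(f"registry file missing columns: {missing_cols}")
    df = df[REGISTRY_COLUMNS].copy()
    df = df.apply(lambda s: s.str.strip())
    df = df.replace("", np.nan)

    codes = df["icd10"].str.upper()
    bad = codes.notna() & ~codes.str.match(_CODE_RE)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise RegistryParseError(
            f"row {row}, column 'icd10': invalid ICD-10 code {df['icd10'].iloc[row]!r}"
        )
    df["icd10"] = codes

    adm = df["admitted"]
    bad = adm.notna() & ~adm.isin(["0", "1"])
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise RegistryParseError(
            f"row {row}, column 'admitted': expected 0/1, got {adm.iloc[row]!r}"
        )

    int_cols = ["sbp", "pulse", "cci", "prior_ed", "prior_inpt", "prior_surg",
                "prior_icu", "prior_hd", "prior_ica", "prior_infect"]
    float_cols = ["age", "temp"]
    for col in int_cols + float_cols + ["admitted"]:
        raw = df[col]
        parsed = pd.to_numeric(raw, errors="coerce")
        bad = raw.notna() & parsed.isna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise RegistryParseError(
                f"row {row}, column {col!r}: non-numeric value {raw.iloc[row]!r}"
            )
        df[col] = parsed
    for col in int_cols + ["admitted"]:
        if df[col].notna().all():
            df[col] = df[col].astype(int)
    return df
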