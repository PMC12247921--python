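"""Synthetic datasets: WTP bids, BDM auctions, choices, multivoxel patterns.

The generators reproduce the statistical structure of a three-day bundle
valuation study: right-skewed item values on a $0-$20 budget, bundle bids
produced by one of four value-aggregation families with subject-level
random effects and censoring at the budget bounds, a Becker-DeGroot-Marschak
auction, logistic choices against per-category median references, and
trial-wise multivoxel response patterns that encode value under a selectable
coding scheme (absolute, subtractive, z-score, compressive normalization
with bundle attenuation, or null) on fixed random encoding directions with
additive Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .design import StimulusCatalog, enumerate_bundles

FAMILIES = ("linear", "power", "logarithmic", "divnorm")
SCHEMES = ("absolute", "subtractive", "zscore", "full_normalization", "null")

BID_MIN, BID_MAX = 0.0, 20.0

#: default generating parameters per family, chosen to give bundle bids in
#: the empirically typical $4-$6 range for typical item values
DEFAULT_PARAMS: dict[str, dict[str, float]] = {
    "linear": {"beta0": 0.83, "beta1": 0.73, "beta2": 0.73},
    "power": {"beta0": 0.5, "beta1": 1.2, "beta2": 0.8, "beta3": 1.2, "beta4": 0.8},
    "logarithmic": {"beta0": 0.3, "beta1": 3.0, "beta3": 1.0, "beta4": 3.0, "beta5": 1.0},
    "divnorm": {"beta0": 0.5, "beta1": 18.0, "sigma": 15.0},
}


class ParameterError(ValueError):
    """Raised for invalid generative parameters."""


def bundle_value(family: str, vi, vj, params: dict[str, float]):
    """Predicted bundle value under one of the four aggregation families.

    linear       b0 + b1*vi + b2*vj
    power        b0 + b1*vi**b2 + b3*vj**b4
    logarithmic  b0 + b1*log(b3 + vi) + b4*log(b5 + vj)
    divnorm      b0 + b1*(vi + vj)/(sigma + vi + vj)
    """
    vi = np.asarray(vi, dtype=float)
    vj = np.asarray(vj, dtype=float)
    p = params
    if family == "linear":
        return p["beta0"] + p["beta1"] * vi + p["beta2"] * vj
    if family == "power":
        return p["beta0"] + p["beta1"] * vi ** p["beta2"] + p["beta3"] * vj ** p["beta4"]
    if family == "logarithmic":
        return (
            p["beta0"]
            + p["beta1"] * np.log(p["beta3"] + vi)
            + p["beta4"] * np.log(p["beta5"] + vj)
        )
    if family == "divnorm":
        if p["sigma"] <= 0:
            raise ParameterError("divnorm requires sigma > 0")
        vbar = vi + vj
        return p["beta0"] + p["beta1"] * vbar / (p["sigma"] + vbar)
    raise ParameterError(f"unknown family {family!r}")


@dataclass
class GenerativeBundleSpec:
    """Generating model for synthetic WTP data.

    Latent item values are drawn from an exponential distribution truncated
    to the $0-$20 budget (mean 3.3 by default, mimicking the right-skewed
    empirical bid distributions); bundle bids follow ``family`` applied to
    the latent item values plus subject random effects (intercept and scale
    slope) and additive Gaussian noise, censored to the budget.
    """

    family: str = "divnorm"
    params: dict[str, float] = field(default_factory=dict)
    re_sd_intercept: float = 0.3
    re_sd_slope: float = 0.05
    noise_sd: float = 1.0
    item_noise_sd: float = 0.5
    value_mean: float = 3.3
    censor_bids: bool = True  # clip recorded bids to the $0-$20 budget

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ParameterError(f"unknown family {self.family!r}")
        merged = dict(DEFAULT_PARAMS[self.family])
        merged.update(self.params)
        self.params = merged
        if self.family == "divnorm" and self.params["sigma"] <= 0:
            raise ParameterError("divnorm requires sigma > 0")
        if self.noise_sd < 0 or self.item_noise_sd < 0:
            raise ParameterError("noise sd must be non-negative")


def _draw_latent_values(rng: np.random.Generator, n: int, mean: float) -> np.ndarray:
    # exponential truncated to the budget; inverse-CDF keeps determinism simple
    u = rng.uniform(size=n)
    cap = 1.0 - np.exp(-BID_MAX / mean)
    return -mean * np.log1p(-u * cap)


def _apply_random_effects(spec: GenerativeBundleSpec, params, u0, u1):
    p = dict(params)
    p["beta0"] = p["beta0"] + u0
    if spec.family == "linear":
        p["beta1"] = p["beta1"] + u1
        p["beta2"] = p["beta2"] + u1
    else:
        p["beta1"] = p["beta1"] + u1
    return p


def simulate_wtp_dataset(
    spec: GenerativeBundleSpec,
    catalog: StimulusCatalog,
    n_subjects: int = 14,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-subject WTP bids for every day-roster item and bundle.

    Returns a tidy frame (one row per elicited bid) with latent generating
    values retained for parameter-recovery tests. Bids are censored to
    [$0, $20].
    """
    if n_subjects < 1:
        raise ParameterError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(1, n_subjects + 1):
        latent = {
            int(i): v
            for i, v in zip(
                catalog.items.item_id,
                _draw_latent_values(rng, catalog.n_items, spec.value_mean),
            )
        }
        u0 = rng.normal(0.0, spec.re_sd_intercept) if spec.re_sd_intercept > 0 else 0.0
        u1 = rng.normal(0.0, spec.re_sd_slope) if spec.re_sd_slope > 0 else 0.0
        p_s = _apply_random_effects(spec, spec.params, u0, u1)
        for day, roster in catalog.day_rosters.items():
            for i in roster:
                bid = latent[i] + (
                    rng.normal(0.0, spec.item_noise_sd) if spec.item_noise_sd else 0.0
                )
                rows.append(
                    {
                        "subject_id": s,
                        "day": day,
                        "trial_type": "item",
                        "item_id": i,
                        "left_item": pd.NA,
                        "right_item": pd.NA,
                        "category": catalog.category_of(i),
                        "bundle_type": pd.NA,
                        "bid": float(np.clip(bid, BID_MIN, BID_MAX))
                        if spec.censor_bids else float(bid),
                        "latent_value": latent[i],
                    }
                )
            for b in enumerate_bundles(roster, catalog):
                vi, vj = latent[b.left_item], latent[b.right_item]
                mu = float(bundle_value(spec.family, vi, vj, p_s))
                bid = mu + (rng.normal(0.0, spec.noise_sd) if spec.noise_sd else 0.0)
                rows.append(
                    {
                        "subject_id": s,
                        "day": day,
                        "trial_type": "bundle",
                        "item_id": pd.NA,
                        "left_item": b.left_item,
                        "right_item": b.right_item,
                        "category": pd.NA,
                        "bundle_type": b.bundle_type,
                        "bid": float(np.clip(bid, BID_MIN, BID_MAX))
                        if spec.censor_bids else float(bid),
                        "latent_value": mu,
                    }
                )
    return pd.DataFrame(rows)


def simulate_bdm_outcome(
    bid: float, seed: int | np.random.Generator = 0
) -> tuple[bool, float]:
    """One Becker-DeGroot-Marschak auction: bid vs a Uniform($0,$20) price.

    The stimulus is purchased iff the bid meets the drawn price, and the
    price (not the bid) is paid — truthful bidding is therefore optimal.
    """
    if not BID_MIN <= bid <= BID_MAX:
        raise ParameterError(f"bid {bid} outside [{BID_MIN}, {BID_MAX}]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    price = float(rng.uniform(BID_MIN, BID_MAX))
    purchased = bid >= price
    return purchased, price if purchased else 0.0


def expected_bdm_surplus(bid: float, true_value: float) -> float:
    """Closed-form expected surplus E[(v - price) * 1(bid >= price)] under BDM."""
    # price ~ U(0,20): integral_0^bid (v - p)/20 dp
    return (true_value * bid - bid**2 / 2.0) / (BID_MAX - BID_MIN)


def simulate_choices(
    schedule: pd.DataFrame,
    wtp: pd.DataFrame,
    temperature: float = 1.0,
    money_bias: float = 0.0,
    seed: int = 0,
    rt_mu: float = 0.0,
    rt_sigma: float = 0.4,
) -> pd.DataFrame:
    """Logistic choices of stimulus vs. the reference monetary amount.

    P(choose stimulus) = logistic((bid - reference - money_bias*[item]) /
    temperature); a positive ``money_bias`` pushes single-item trials toward
    the money, as reported empirically. Reaction times are log-normal
    plumbing.
    """
    if temperature <= 0:
        raise ParameterError("temperature must be positive")
    rng = np.random.default_rng(seed)
    bids = attach_bids(schedule, wtp)
    dv = bids - schedule.reference_amount.to_numpy(float)
    dv = dv - money_bias * (schedule.trial_type.to_numpy() == "item")
    p = stats.logistic.cdf(dv / temperature)
    chose = rng.uniform(size=len(p)) < p
    out = schedule.copy()
    out["bid"] = bids
    out["p_stimulus"] = p
    out["chose_stimulus"] = chose
    out["rt"] = rng.lognormal(rt_mu, rt_sigma, size=len(p))
    return out


def attach_bids(schedule: pd.DataFrame, wtp: pd.DataFrame) -> np.ndarray:
    """Look up the WTP bid for every scheduled trial (same subject and day)."""
    item_key = {}
    bundle_key = {}
    for r in wtp.itertuples(index=False):
        if r.trial_type == "item":
            item_key[(r.subject_id, r.day, int(r.item_id))] = r.bid
        else:
            bundle_key[(r.subject_id, r.day, int(r.left_item), int(r.right_item))] = r.bid
    bids = np.empty(len(schedule))
    for k, r in enumerate(schedule.itertuples(index=False)):
        if r.trial_type == "item":
            bids[k] = item_key[(r.subject_id, r.day, int(r.item_id))]
        else:
            bids[k] = bundle_key[(r.subject_id, r.day, int(r.left_item), int(r.right_item))]
    return bids


@dataclass
class CodingScheme:
    """How trial value is written into multivoxel patterns.

    ``scheme`` selects the coded value: the raw bid (absolute), the bid
    minus its trial-type mean (subtractive), the within-trial-type z-score
    (zscore), a compressive normalization v/(sigma + v) with trial-type
    attenuation (full_normalization), or no value signal at all (null).
    ``w_item``/``w_bundle`` scale the value signal per trial type — a
    ``w_bundle < w_item`` realizes attenuation of the bundle value code.
    ``separate_directions`` encodes item and bundle value on orthogonalized
    random directions instead of a shared one (a condition-specific code).
    """

    scheme: str = "zscore"
    w_item: float = 1.0
    w_bundle: float = 1.0
    w_trial_type: float = 0.5
    w_side: float = 0.5
    noise_sd: float = 1.0
    n_voxels: int = 200
    sigma: float = 5.0
    separate_directions: bool = False
    encoding_seed: int = 12345

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ParameterError(f"unknown scheme {self.scheme!r}")
        if self.n_voxels < 2:
            raise ParameterError("n_voxels must be >= 2")
        if self.noise_sd < 0:
            raise ParameterError("noise sd must be non-negative")
        if self.scheme == "null":
            self.w_item = 0.0
            self.w_bundle = 0.0

    def with_attenuation(self, ratio: float) -> "CodingScheme":
        """Copy with the bundle value weight set to ratio * w_item."""
        return replace(self, w_bundle=ratio * self.w_item)


@dataclass
class VoxelPatternDataset:
    """Trials x voxels response patterns for one ROI with trial metadata."""

    patterns: np.ndarray
    meta: pd.DataFrame  # value, coded_value, trial_type, day, run, button_side, ...
    roi_label: str = "roi"

    def __post_init__(self) -> None:
        if len(self.patterns) != len(self.meta):
            raise ParameterError(
                f"pattern rows ({len(self.patterns)}) != metadata rows "
                f"({len(self.meta)})"
            )
        if not np.all(np.isfinite(self.patterns)):
            raise ParameterError("non-finite pattern entries")

    @property
    def n_trials(self) -> int:
        return len(self.meta)

    @property
    def n_voxels(self) -> int:
        return self.patterns.shape[1]


def coded_values(values: np.ndarray, trial_types: np.ndarray, scheme: CodingScheme):
    """Transform raw bids into the scheme's coded value, per trial type."""
    values = np.asarray(values, dtype=float)
    out = np.array(values)
    if scheme.scheme in ("absolute", "null"):
        return out
    for tt in np.unique(trial_types):
        m = trial_types == tt
        if scheme.scheme == "subtractive":
            out[m] = values[m] - values[m].mean()
        elif scheme.scheme == "zscore":
            sd = values[m].std()
            if sd == 0:
                raise ParameterError(f"constant values in condition {tt!r}")
            out[m] = (values[m] - values[m].mean()) / sd
        elif scheme.scheme == "full_normalization":
            out[m] = values[m] / (scheme.sigma + values[m])
    return out


def _unit(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=n)
    return v / np.linalg.norm(v)


def simulate_voxel_patterns(
    schedule: pd.DataFrame,
    wtp: pd.DataFrame,
    scheme: CodingScheme,
    seed: int = 0,
    roi_label: str = "roi",
    subject_id: int | None = None,
) -> VoxelPatternDataset:
    """Trial-wise patterns: value signal + nuisance structure + noise.

    pattern(t) = w_value(type)*coded_value(t)*u + w_tt*[bundle]*c
                 + w_side*[right]*s + eps,
    with u, c, s fixed unit-norm directions drawn once from the encoding
    seed and eps i.i.d. Gaussian. Stands in for trial-wise beta maps.
    """
    sched = schedule if subject_id is None else schedule[schedule.subject_id == subject_id]
    sched = sched.reset_index(drop=True)
    enc = np.random.default_rng(scheme.encoding_seed)
    u_item = _unit(enc, scheme.n_voxels)
    if scheme.separate_directions:
        raw = _unit(enc, scheme.n_voxels)
        raw = raw - (raw @ u_item) * u_item  # orthogonalize
        u_bundle = raw / np.linalg.norm(raw)
    else:
        u_bundle = u_item
    c_dir = _unit(enc, scheme.n_voxels)
    s_dir = _unit(enc, scheme.n_voxels)

    rng = np.random.default_rng(seed)
    values = attach_bids(sched, wtp)
    tts = sched.trial_type.to_numpy()
    coded = coded_values(values, tts, scheme)
    is_bundle = (tts == "bundle").astype(float)
    is_right = (sched.item_side.to_numpy() == "right").astype(float)

    w_val = np.where(tts == "item", scheme.w_item, scheme.w_bundle)
    u_mat = np.where(tts[:, None] == "item", u_item[None, :], u_bundle[None, :])
    patterns = (
        (w_val * coded)[:, None] * u_mat
        + (scheme.w_trial_type * is_bundle)[:, None] * c_dir[None, :]
        + (scheme.w_side * is_right)[:, None] * s_dir[None, :]
    )
    if scheme.noise_sd:
        patterns = patterns + rng.normal(0.0, scheme.noise_sd, size=patterns.shape)

    meta = sched[
        ["subject_id", "day", "run", "trial_index", "trial_type", "item_side",
         "reference_amount"]
    ].copy()
    meta["button_side"] = meta.pop("item_side")
    meta["value"] = values
    meta["coded_value"] = coded
    return VoxelPatternDataset(patterns=patterns, meta=meta, roi_label=roi_label)
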