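"""Synthetic cohorts with known ground truth.

The study design being emulated is a cross-sectional ageing cohort of
healthy older (HO) and mild-cognitive-impairment (MCI) participants
carrying

* a battery of cognitive scores generated from a global-cognition factor
  with nested executive and memory factors,
* ROI-to-ROI Fisher-z connectivity indicators generated from per-network
  connectivity factors,
* a right-skewed white-matter-lesion load (percent of intracranial
  volume) drawn from a truncated log-normal,
* a built-in lesion x connectivity interaction on the cognition factors,
* group mean shifts and structured missingness.

Because every structural coefficient used in generation is known, each
downstream estimator can be validated by parameter recovery.

Reproducibility contract: each random component (latent block, lesion
draws, each indicator, each missingness mask) gets its own stream keyed
by ``(seed, crc32(name))``, so the same seed gives a byte-identical
table and adding a new variable to a config does not perturb existing
columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence
from zlib import crc32

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import SpecificationError

__all__ = ["CohortConfig", "SubjectTable", "generate_cohort", "inject_missingness"]

HO, MCI = "HO", "MCI"
_COGNITION_LATENTS = ("g", "ef", "memory")


def _rng_for(seed: int, name: str) -> np.random.Generator:
    """Independent stream for one named component of a cohort."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, crc32(name.encode())])


class SubjectTable:
    """Subject x variable data with explicit missingness and group labels.

    Thin wrapper around a :class:`pandas.DataFrame`; missing entries are
    NaN, the group label lives in the ``group`` column and is never
    missing.
    """

    GROUP_COL = "group"

    def __init__(self, data: pd.DataFrame):
        if self.GROUP_COL not in data.columns:
            raise SpecificationError("table must carry a 'group' column")
        if data[self.GROUP_COL].isna().any():
            raise SpecificationError("group label must never be missing")
        self.data = data.reset_index(drop=True)

    def __len__(self):
        return len(self.data)

    @property
    def group(self) -> pd.Series:
        return self.data[self.GROUP_COL]

    @property
    def variables(self) -> list[str]:
        return [c for c in self.data.columns if c != self.GROUP_COL]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.data[self.variables].isna()

    def numeric(self, columns: Sequence[str]) -> np.ndarray:
        missing = [c for c in columns if c not in self.data.columns]
        if missing:
            raise SpecificationError(f"variables not in table: {missing}")
        return self.data[list(columns)].to_numpy(dtype=float)

    def to_csv(self, path):
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path):
        return cls(pd.read_csv(path))

    @classmethod
    def from_dataframe(cls, df):
        return cls(df)


def as_subject_table(table) -> SubjectTable:
    if isinstance(table, SubjectTable):
        return table
    return SubjectTable(table)


@dataclass
class CohortConfig:
    """Generating model for one synthetic cohort.

    Parameters
    ----------
    n_total, n_mci : int
        Cohort size and number of MCI participants (listed after the HO
        block; rows are exchangeable).
    exogenous_latents : list of str
        Names of the latent variables drawn directly from
        ``latent_covariances`` (connectivity networks, cognitive reserve,
        ...). The cognition latents ``g``, ``ef``, ``memory`` are instead
        endogenous: they receive the structural effects below.
    latent_covariances : ndarray
        Covariance of the exogenous latents (PSD, order as in
        ``exogenous_latents``).
    loading_matrix : mapping latent -> list of (indicator, loading)
        Measurement model. An indicator may appear under several latents
        (nested-factor structure); contributions add.
    structural : mapping
        Keys among ``beta_wml_g``, ``beta_wml_ef``, ``beta_wml_mem``,
        ``beta_conn_ef``, ``beta_conn_mem``, ``omega_ef``, ``omega_mem``,
        plus optional ``beta_cvd_wml_meanlog``, ``beta_cvd_ef``,
        ``beta_cvd_mem``. ``omega_*`` multiply the product of the
        (mean-centred) lesion load with the moderator latent.
    moderator : str
        Which exogenous latent moderates the lesion effect.
    wml_distribution : mapping
        ``meanlog``, ``sdlog``, ``max`` of the truncated log-normal
        lesion load on the percent-of-TIV scale.
    residual_sd : mapping indicator -> float
        Indicator residual standard deviations (default 0.6).
    indicator_means : mapping indicator -> float
        Indicator intercepts (default 0).
    residual_covariances : list of (indicator, indicator, cov)
        Residual covariances among indicators (e.g. connectivity pairs
        sharing a seed region).
    group_shifts : mapping name -> float
        Mean shift applied to MCI rows; keys may be latent names,
        ``wml_meanlog``, or extra-observed names.
    extra_observed : mapping name -> {mean, sd, group_shift}
        Additional independent Gaussian observed variables (age, grey
        matter volume, CVD risk, ...).
    missingness : mapping variable -> spec
        Passed to :func:`inject_missingness` after generation.
    structural_residual_sd : mapping latent -> float
        SD of the disturbance of each cognition latent (default 1,
        matching the fixed-unit-variance identification downstream).
    wml_transform : {"raw", "log1p"}
        Whether analyses downstream should use the raw percent ratio or
        its log1p transform; the generator always emits both columns.
    """

    n_total: int = 230
    n_mci: int = 90
    exogenous_latents: Sequence[str] = field(default_factory=lambda: ["conn"])
    latent_covariances: np.ndarray | None = None
    loading_matrix: Mapping[str, Sequence[tuple]] = field(default_factory=dict)
    structural: Mapping[str, float] = field(default_factory=dict)
    structural_group_overrides: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    moderator: str = "conn"
    wml_distribution: Mapping[str, float] = field(
        default_factory=lambda: {"meanlog": -2.646, "sdlog": 1.322, "max": 2.8}
    )
    residual_sd: Mapping[str, float] = field(default_factory=dict)
    indicator_means: Mapping[str, float] = field(default_factory=dict)
    residual_covariances: Sequence[tuple] = field(default_factory=list)
    group_shifts: Mapping[str, float] = field(default_factory=dict)
    extra_observed: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    missingness: Mapping[str, Mapping] = field(default_factory=dict)
    structural_residual_sd: Mapping[str, float] = field(default_factory=dict)
    wml_transform: str = "raw"
    seed: int = 0

    def __post_init__(self):
        if self.n_mci > self.n_total:
            raise SpecificationError("n_mci must not exceed n_total")
        k = len(self.exogenous_latents)
        if self.latent_covariances is None:
            self.latent_covariances = np.eye(k)
        self.latent_covariances = np.asarray(self.latent_covariances, dtype=float)
        if self.latent_covariances.shape != (k, k):
            raise SpecificationError("latent_covariances shape mismatch")
        if not np.allclose(self.latent_covariances, self.latent_covariances.T):
            raise SpecificationError("latent_covariances must be symmetric")
        ev = np.linalg.eigvalsh(self.latent_covariances)
        if ev.min() < -1e-10:
            raise SpecificationError("latent_covariances must be positive semi-definite")
        for var, spec in self.missingness.items():
            rate = float(spec.get("rate", 0.0))
            if not 0.0 <= rate <= 1.0:
                raise SpecificationError(f"missingness rate for {var} outside [0, 1]")
        if self.moderator not in self.exogenous_latents:
            raise SpecificationError(f"moderator {self.moderator!r} is not an exogenous latent")
        if self.wml_transform not in ("raw", "log1p"):
            raise SpecificationError("wml_transform must be 'raw' or 'log1p'")

    @property
    def indicators(self) -> list[str]:
        seen: list[str] = []
        for lat in self.loading_matrix:
            for ind, _ in self.loading_matrix[lat]:
                if ind not in seen:
                    seen.append(ind)
        return seen

    @property
    def wml_column(self) -> str:
        """Column downstream analyses should use as the lesion predictor."""
        return "wml_ratio" if self.wml_transform == "raw" else "wml_ratio_log"

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping):
        raw = dict(raw)
        if "loading_matrix" in raw:
            raw["loading_matrix"] = {
                lat: [tuple(pair) for pair in pairs]
                for lat, pairs in raw["loading_matrix"].items()
            }
        if "latent_covariances" in raw and raw["latent_covariances"] is not None:
            raw["latent_covariances"] = np.asarray(raw["latent_covariances"], dtype=float)
        if "residual_covariances" in raw:
            raw["residual_covariances"] = [tuple(t) for t in raw["residual_covariances"]]
        return cls(**raw)


def _truncated_lognormal(meanlog, sdlog, upper, size, rng):
    """Inverse-CDF sampling of a log-normal truncated at ``upper``."""
    dist = stats.lognorm(s=sdlog, scale=np.exp(meanlog))
    cap = dist.cdf(upper)
    u = rng.uniform(0.0, cap, size=size)
    return dist.ppf(u)


def generate_cohort(config: CohortConfig) -> SubjectTable:
    """Draw one cohort from the generating model in ``config``.

    Order of construction: group labels, exogenous latents, lesion load,
    cognition latents (with the lesion x connectivity product term),
    indicators, extra observed variables, then missingness.
    """
    n, n_mci = config.n_total, config.n_mci
    seed = config.seed
    group = np.array([HO] * (n - n_mci) + [MCI] * n_mci)
    is_mci = group == MCI

    # exogenous latents
    k = len(config.exogenous_latents)
    w, V = np.linalg.eigh(config.latent_covariances)
    root = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = _rng_for(seed, "exogenous_latents").standard_normal((n, k))
    exo = z @ root.T
    latents = {name: exo[:, j].copy() for j, name in enumerate(config.exogenous_latents)}
    for name in config.exogenous_latents:
        if name in config.group_shifts:
            latents[name] = latents[name] + config.group_shifts[name] * is_mci

    # extra observed (needed before WML if CVD feeds the lesion model)
    extras = {}
    for name, spec in config.extra_observed.items():
        r = _rng_for(seed, f"extra:{name}")
        vals = spec.get("mean", 0.0) + spec.get("sd", 1.0) * r.standard_normal(n)
        vals = vals + spec.get("group_shift", 0.0) * is_mci
        extras[name] = vals

    s = dict(config.structural)
    wd = config.wml_distribution
    meanlog = np.full(n, float(wd["meanlog"]))
    meanlog += config.group_shifts.get("wml_meanlog", 0.0) * is_mci
    if "beta_cvd_wml_meanlog" in s and "cvd_risk" in extras:
        cvd = extras["cvd_risk"]
        cvd_z = (cvd - cvd.mean()) / cvd.std(ddof=0)
        meanlog = meanlog + s["beta_cvd_wml_meanlog"] * cvd_z
    rw = _rng_for(seed, "wml")
    dist_u = rw.uniform(0.0, 1.0, size=n)
    base = stats.lognorm(s=float(wd["sdlog"]), scale=1.0)
    cap = base.cdf(float(wd["max"]) / np.exp(meanlog))
    wml = np.exp(meanlog) * base.ppf(dist_u * cap)

    wml_pred = np.log1p(wml) if config.wml_transform == "log1p" else wml
    wml_c = wml_pred - wml_pred.mean()
    mod = latents[config.moderator]

    # per-row structural coefficients (group-specific overrides allowed,
    # e.g. an interaction present only in the MCI class)
    def coef(key):
        base_val = s.get(key, 0.0)
        vals = np.full(n, base_val)
        for grp, over in config.structural_group_overrides.items():
            if key in over:
                vals[group == grp] = over[key]
        return vals

    # cognition latents (disturbance sd defaults to 1 = downstream scaling)
    for lat, bw, bc, om, bcvd in (
        ("g", "beta_wml_g", "beta_conn_g", "omega_g", "beta_cvd_g"),
        ("ef", "beta_wml_ef", "beta_conn_ef", "omega_ef", "beta_cvd_ef"),
        ("memory", "beta_wml_mem", "beta_conn_mem", "omega_mem", "beta_cvd_mem"),
    ):
        if lat not in config.loading_matrix:
            continue
        zeta_sd = config.structural_residual_sd.get(lat, 1.0)
        val = zeta_sd * _rng_for(seed, f"zeta:{lat}").standard_normal(n)
        val = val + coef(bw) * wml_c
        val = val + coef(bc) * mod
        val = val + coef(om) * wml_c * mod
        if bcvd in s and "cvd_risk" in extras:
            cvd = extras["cvd_risk"]
            val = val + s[bcvd] * (cvd - cvd.mean()) / cvd.std(ddof=0)
        val = val + config.group_shifts.get(lat, 0.0) * is_mci
        latents[lat] = val

    # indicators = sum of loading * latent + residual
    inds = config.indicators
    signal = {ind: np.full(n, config.indicator_means.get(ind, 0.0)) for ind in inds}
    for lat, pairs in config.loading_matrix.items():
        if lat not in latents:
            raise SpecificationError(f"loading matrix references unknown latent {lat!r}")
        for ind, loading in pairs:
            signal[ind] = signal[ind] + float(loading) * latents[lat]

    # residuals: indicators tied by a residual covariance are drawn jointly
    comp_of = {ind: frozenset([ind]) for ind in inds}
    for a, b, _ in config.residual_covariances:
        merged = comp_of[a] | comp_of[b]
        for m in merged:
            comp_of[m] = merged
    columns = {}
    done: set[frozenset] = set()
    for ind in inds:
        comp = comp_of[ind]
        if comp in done:
            continue
        done.add(comp)
        members = sorted(comp)
        sds = np.array([config.residual_sd.get(m, 0.6) for m in members])
        cov = np.diag(sds**2)
        idx = {m: j for j, m in enumerate(members)}
        for a, b, c in config.residual_covariances:
            if a in idx and b in idx:
                cov[idx[a], idx[b]] = cov[idx[b], idx[a]] = c
        evals, evecs = np.linalg.eigh(cov)
        if evals.min() < -1e-10:
            raise SpecificationError("residual covariance block not PSD")
        rroot = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None)))
        draws = _rng_for(seed, "resid:" + "+".join(members)).standard_normal((n, len(members)))
        resid = draws @ rroot.T
        for m in members:
            columns[m] = signal[m] + resid[:, idx[m]]

    data = pd.DataFrame({"subject_id": [f"S{i:04d}" for i in range(n)], "group": group})
    for ind in inds:
        data[ind] = columns[ind]
    data["wml_ratio"] = wml
    data["wml_ratio_log"] = np.log1p(wml)
    for name in config.extra_observed:
        data[name] = extras[name]
    # ground-truth latent scores, for recovery checks only
    for lat, vals in latents.items():
        data[f"true_{lat}"] = vals

    table = SubjectTable(data)
    if config.missingness:
        table = inject_missingness(table, config.missingness, seed=seed)
    return table


def inject_missingness(table, spec: Mapping[str, Mapping], seed: int = 0) -> SubjectTable:
    """Mask entries of a cohort table according to a missingness plan.

    ``spec`` maps variable name to a dict with keys

    * ``rate`` — fraction in [0, 1] of eligible rows to mask,
    * ``mechanism`` — ``"MCAR"`` (default) or ``"MAR-on-group"``,
    * ``group`` — eligible group for ``MAR-on-group``,
    * ``exact`` — if true, mask exactly ``round(rate * n_eligible)``
      entries; otherwise each eligible entry is masked independently.

    Observed values are untouched; only the mask (NaN pattern) changes.
    """
    table = as_subject_table(table)
    data = table.data.copy()
    n = len(data)
    for var in sorted(spec):
        plan = spec[var]
        if var not in data.columns:
            raise SpecificationError(f"missingness on unknown variable {var!r}")
        rate = float(plan.get("rate", 0.0))
        if not 0.0 <= rate <= 1.0:
            raise SpecificationError(f"missingness rate for {var} outside [0, 1]")
        if rate == 0.0:
            continue
        mech = plan.get("mechanism", "MCAR")
        eligible = np.ones(n, dtype=bool)
        if mech == "MAR-on-group":
            eligible = (data["group"] == plan.get("group", MCI)).to_numpy()
        elif mech != "MCAR":
            raise SpecificationError(f"unknown missingness mechanism {mech!r}")
        rng = _rng_for(seed, f"missing:{var}")
        idx = np.flatnonzero(eligible)
        if plan.get("exact", False):
            k = int(round(rate * idx.size))
            chosen = rng.choice(idx, size=k, replace=False)
        else:
            chosen = idx[rng.uniform(size=idx.size) < rate]
        data.loc[chosen, var] = np.nan
    return SubjectTable(data)


def generate_mediation_cohort(
    n: int,
    a: float,
    b: float,
    c_prime: float = 0.0,
    loadings=(0.8, 0.7, 0.6),
    residual_sd=(0.6, 0.6, 0.6),
    outcome_name: str = "ef",
    seed: int = 0,
) -> SubjectTable:
    """Minimal predictor -> mediator -> latent-outcome chain.

    ``cvd_risk`` is standard normal, ``wml_ratio = a * cvd + e`` with unit
    disturbance, and the latent outcome is ``b * wml + c' * cvd + zeta``
    measured by three indicators. Used for validating the mediation
    machinery against known path coefficients.
    """
    r = _rng_for(seed, "mediation")
    cvd = r.standard_normal(n)
    wml = a * cvd + r.standard_normal(n)
    eta = b * wml + c_prime * cvd + r.standard_normal(n)
    data = {"subject_id": [f"S{i:04d}" for i in range(n)], "group": [HO] * n,
            "cvd_risk": cvd, "wml_ratio": wml, f"true_{outcome_name}": eta}
    for j, (lam, sd) in enumerate(zip(loadings, residual_sd), start=1):
        data[f"{outcome_name}_ind{j}"] = lam * eta + sd * r.standard_normal(n)
    return SubjectTable(pd.DataFrame(data))
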