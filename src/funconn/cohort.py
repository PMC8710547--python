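"""Synthetic three-group cohort generator.

Emulates the data structure of a hemodialysis cognitive-impairment
connectome study: healthy controls (HC), patients without cognitive
impairment (MHD_noCI) and patients with cognitive impairment (MHD_CI),
each subject contributing a T x N matrix of regional BOLD-like signals, a
six-parameter head-motion trace, surrogate nuisance signals, and a
metadata row (demographics, mood scores, cognition scores).

Ground truth is a modular (stochastic-block) covariance: regions fall
into equally sized modules with within-module correlation rho_w (a
per-group effect, HC highest) and a fixed low between-module correlation.
Time series are stationary Gaussian AR(1) processes with that spatial
covariance, so the planted group effect lives entirely in second-order
structure — exactly what partial-correlation networks estimate.
Cognition scores are a linear function of each subject's realized rho_w
plus noise, planting a positive clustering–cognition association among
patients; the MoCA-based grouping rule (CI iff MoCA < 26 among patients)
is enforced exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "GROUPS",
    "CohortConfig",
    "Cohort",
    "generate_cohort",
    "inject_motion_artifact",
    "write_cohort",
    "read_cohort",
    "load_time_series",
    "load_motion_trace",
]

GROUPS = ("HC", "MHD_noCI", "MHD_CI")

#: Per-group male fraction, age, SDS/SAS locations loosely matching a
#: typical hemodialysis cohort (controls community-recruited).
_GROUP_PROFILE = {
    "HC": dict(p_male=12 / 25, age=(55.0, 9.0), sds=33.0, sas=31.0, edu=11.0),
    "MHD_noCI": dict(p_male=16 / 20, age=(48.0, 8.0), sds=39.0, sas=36.0, edu=11.0),
    "MHD_CI": dict(p_male=13 / 19, age=(56.0, 7.0), sds=44.0, sas=37.0, edu=9.5),
}


@dataclass
class CohortConfig:
    """Everything that determines a synthetic cohort given a seed."""

    n_per_group: tuple[int, int, int] = (25, 20, 19)
    n_regions: int = 90
    n_volumes: int = 240
    tr_seconds: float = 2.0
    module_count: int = 22
    within_module_corr: dict[str, float] = field(
        default_factory=lambda: {"HC": 0.55, "MHD_noCI": 0.44, "MHD_CI": 0.33}
    )
    between_module_corr: float = 0.05
    corr_jitter_sd: float = 0.025
    ar_coefficient: float = 0.4
    noise_sd: float = 1.0
    cognition_link: float = 2.0
    motion_step_sd: float = 0.02
    seed: int = 2021

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.n_per_group):
            raise ValueError("every group needs at least 2 subjects")
        if not all(0.0 <= v < 1.0 for v in self.within_module_corr.values()):
            raise ValueError("within_module_corr values must be in [0, 1)")
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must be in [0, 1)")
        if self.module_count < 1 or self.module_count > self.n_regions:
            raise ValueError("module_count must be in [1, n_regions]")
        w = self.within_module_corr
        if not (w["HC"] >= w["MHD_noCI"] >= w["MHD_CI"]):
            warnings.warn(
                "within-module correlation does not follow HC >= MHD_noCI >= "
                "MHD_CI; the planted ordering is inverted or absent"
            )


@dataclass
class Cohort:
    series: dict[str, np.ndarray]
    meta: pd.DataFrame
    motion: dict[str, np.ndarray]
    nuisance: dict[str, np.ndarray]

    @property
    def subject_ids(self) -> list[str]:
        return list(self.meta["subject_id"])


def module_assignment(n_regions: int, module_count: int) -> np.ndarray:
    """Region -> module labels, modules as equal-sized as possible."""
    return np.sort(np.arange(n_regions) % module_count)


def block_covariance(
    n_regions: int, module_count: int, rho_w: float, rho_b: float, scale: float = 1.0
) -> np.ndarray:
    """Modular correlation matrix: rho_w within modules, rho_b between."""
    mods = module_assignment(n_regions, module_count)
    same = mods[:, None] == mods[None, :]
    r = np.where(same, rho_w, rho_b)
    np.fill_diagonal(r, 1.0)
    # guard positive definiteness for extreme parameter choices
    min_eig = np.linalg.eigvalsh(r)[0]
    if min_eig < 1e-8:
        r += (1e-8 - min_eig) * np.eye(n_regions)
    return scale**2 * r


def sample_ar1_series(
    cov: np.ndarray, n_volumes: int, phi: float, rng: np.random.Generator, burn_in: int = 50
) -> np.ndarray:
    """Stationary Gaussian AR(1) with spatial covariance `cov`.

    x_t = phi x_{t-1} + e_t with e_t ~ N(0, (1 - phi^2) cov), so the
    stationary covariance of x_t is exactly `cov`.
    """
    n = cov.shape[0]
    chol = np.linalg.cholesky((1.0 - phi**2) * cov)
    innov = rng.standard_normal((n_volumes + burn_in, n)) @ chol.T
    x = signal.lfilter([1.0], [1.0, -phi], innov, axis=0)
    return x[burn_in:]


def _random_walk(rng: np.random.Generator, t: int, step_sd: float) -> np.ndarray:
    return np.cumsum(rng.normal(0.0, step_sd, size=(t, 6)), axis=0)


def _cognition_scores(group: str, latent: float, rng: np.random.Generator) -> dict:
    """Map a latent network-integrity score to plausible scale values.

    The MoCA banding enforces the grouping rule exactly: patients with CI
    score below 26, everyone else at or above 26.
    """
    if group == "HC":
        moca = 28.0 + 0.8 * latent
        lo, hi = 26, 30
    elif group == "MHD_noCI":
        moca = 27.0 + 0.8 * latent
        lo, hi = 26, 30
    else:
        moca = 23.5 + 0.8 * latent
        lo, hi = 18, 25
    moca = int(np.clip(round(moca), lo, hi))
    tmt = float(np.clip(55.0 - 8.0 * latent + rng.normal(0, 8.0), 20.0, 180.0))
    dst_f = int(np.clip(round(7.5 + 0.5 * latent + rng.normal(0, 0.8)), 3, 12))
    dst_b = int(np.clip(round(4.5 + 0.5 * latent + rng.normal(0, 0.8)), 2, 9))
    return dict(moca=moca, tmt_a_seconds=round(tmt, 2), dst_f=dst_f, dst_b=dst_b,
                dst_t=dst_f + dst_b)


def generate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Generate the full synthetic cohort; deterministic given the seed."""
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    rho_b = config.between_module_corr
    group_rhos = config.within_module_corr
    rho_center = float(np.mean(list(group_rhos.values())))
    rho_scale = max(config.corr_jitter_sd, 1e-6) + 0.5 * (
        max(group_rhos.values()) - min(group_rhos.values())
    )

    series: dict[str, np.ndarray] = {}
    motion: dict[str, np.ndarray] = {}
    nuisance: dict[str, np.ndarray] = {}
    rows = []
    sid = 0
    for group, n_sub in zip(GROUPS, config.n_per_group):
        prof = _GROUP_PROFILE[group]
        for _ in range(n_sub):
            sid += 1
            subject_id = f"sub-{sid:03d}"
            rho_i = float(
                np.clip(
                    group_rhos[group] + rng.normal(0.0, config.corr_jitter_sd),
                    rho_b + 0.02,
                    0.95,
                )
            )
            cov = block_covariance(
                config.n_regions, config.module_count, rho_i, rho_b, config.noise_sd
            )
            series[subject_id] = sample_ar1_series(
                cov, config.n_volumes, config.ar_coefficient, rng
            )
            motion[subject_id] = _random_walk(rng, config.n_volumes, config.motion_step_sd)
            # WM / CSF surrogate nuisance signals: smooth AR(1) noise
            nz = signal.lfilter([1.0], [1.0, -0.6],
                                rng.standard_normal((config.n_volumes + 20, 2)), axis=0)[20:]
            nuisance[subject_id] = nz

            z = (rho_i - rho_center) / rho_scale
            latent = config.cognition_link * z + rng.normal(0.0, 1.0)
            cog = _cognition_scores(group, latent, rng)
            age_mu, age_sd = prof["age"]
            row = dict(
                subject_id=subject_id,
                group=group,
                age=int(np.clip(round(rng.normal(age_mu, age_sd)), 25, 69)),
                sex="male" if rng.random() < prof["p_male"] else "female",
                education=int(np.clip(round(rng.normal(prof["edu"], 3.0)), 5, 19)),
                bmi=round(float(np.clip(rng.normal(23.0, 2.5), 16, 35)), 2),
                sds_score=round(float(np.clip(rng.normal(prof["sds"], 6.0), 25, 70)), 1),
                sas_score=round(float(np.clip(rng.normal(prof["sas"], 6.0), 25, 70)), 1),
                true_within_corr=rho_i,
                **cog,
            )
            if group == "HC":
                row["dialysis_months"] = np.nan
            else:
                row["dialysis_months"] = round(float(rng.lognormal(3.3, 0.8)), 1)
            rows.append(row)

    meta = pd.DataFrame(rows)
    _assert_grouping_rule(meta)
    return Cohort(series=series, meta=meta, motion=motion, nuisance=nuisance)


def _assert_grouping_rule(meta: pd.DataFrame) -> None:
    patients = meta[meta["group"] != "HC"]
    ci = patients["group"] == "MHD_CI"
    assert (patients.loc[ci, "moca"] < 26).all()
    assert (patients.loc[~ci, "moca"] >= 26).all()


def inject_motion_artifact(
    trace: np.ndarray, spikes: list[tuple[int, float]]
) -> np.ndarray:
    """Add translation spikes (mm, on the x axis) at given volume indices.

    Returns a copy equal to the input except at the spiked volumes."""
    m = np.array(trace, dtype=float, copy=True)
    for idx, mag in spikes:
        if not 0 <= idx < m.shape[0]:
            raise IndexError(f"spike volume {idx} outside trace of length {m.shape[0]}")
        m[idx, 0] += mag
    return m


# ---------------------------------------------------------------------------
# plain-text on-disk format: one whitespace-delimited matrix per subject
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sid in cohort.subject_ids:
        np.savetxt(out / f"{sid}_timeseries.txt", cohort.series[sid], fmt="%.6f")
        np.savetxt(out / f"{sid}_motion.txt", cohort.motion[sid], fmt="%.6f")
        np.savetxt(out / f"{sid}_nuisance.txt", cohort.nuisance[sid], fmt="%.6f")
    cohort.meta.to_csv(out / "participants.csv", index=False)
    return out


def load_time_series(path: str | Path) -> np.ndarray:
    """Read a T x N plain-text matrix (whitespace- or comma-delimited)."""
    path = Path(path)
    try:
        return np.loadtxt(path)
    except ValueError:
        return np.loadtxt(path, delimiter=",")


def load_motion_trace(path: str | Path) -> np.ndarray:
    m = load_time_series(path)
    if m.ndim != 2 or m.shape[1] != 6:
        raise ValueError(f"{path} is not a T x 6 motion trace")
    return m


def read_cohort(data_dir: str | Path) -> Cohort:
    """Load a cohort previously written by `write_cohort`."""
    d = Path(data_dir)
    meta = pd.read_csv(d / "participants.csv")
    series, motion, nuisance = {}, {}, {}
    for sid in meta["subject_id"]:
        series[sid] = load_time_series(d / f"{sid}_timeseries.txt")
        mpath = d / f"{sid}_motion.txt"
        if mpath.exists():
            motion[sid] = load_motion_trace(mpath)
        npath = d / f"{sid}_nuisance.txt"
        if npath.exists():
            nuisance[sid] = load_time_series(npath)
    return Cohort(series=series, meta=meta, motion=motion, nuisance=nuisance)
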