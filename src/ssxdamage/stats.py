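"""Uncertainty and comparison machinery: image bootstrap, Gaussian-mixture
combination, Welch's t-test, and weighted step-size trend assessment."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .core import rng_from, split_seed


@dataclass
class ParameterStat:
    mean: float
    sd: float
    n_replicas: int
    replica_values: np.ndarray


@dataclass
class BootstrapResult:
    parameters: dict[str, ParameterStat]
    n_failed: int = 0

    def __getitem__(self, key: str) -> ParameterStat:
        return self.parameters[key]

    def as_dict(self) -> dict:
        return {
            name: {
                "mean": p.mean, "sd": p.sd, "n_replicas": p.n_replicas,
                "replica_values": np.asarray(p.replica_values).tolist(),
            }
            for name, p in self.parameters.items()
        } | {"n_failed": self.n_failed}


@dataclass
class MixtureSummary:
    components: list[tuple[float, float]]
    overall_mean: float
    overall_sd: float


@dataclass
class WelchResult:
    t_statistic: float
    dof: float
    p_value: float


def draw_with_replacement(
    images: Sequence, n_replicas: int = 100, seed=None
) -> list[list]:
    """Bootstrap replicas of an image set: each replica has the original
    count, drawn uniformly with replacement."""
    if len(images) < 1:
        raise ValueError("need at least one image")
    rng = rng_from(seed)
    n = len(images)
    return [
        [images[j] for j in rng.integers(0, n, size=n)]
        for _ in range(n_replicas)
    ]


def bootstrap_pipeline(
    images: Sequence,
    pipeline: Callable[[Sequence, int], Mapping[str, float]],
    n_replicas: int = 100,
    seed=None,
) -> BootstrapResult:
    """Per-parameter mean/SD over resampled replicas of the image set.

    ``pipeline(images, seed)`` must map a list of images to a mapping of
    parameter name -> value (typically merge -> scramble -> refine ->
    geometry report).  Each replica receives its own derived seed so the
    scramble draws are independent.  Failing replicas are dropped and
    counted; more than 50% failures aborts.
    """
    master = np.random.SeedSequence(
        seed if not isinstance(seed, np.random.Generator) else seed.integers(2**31)
    )
    draw_seed, *replica_seeds = master.spawn(n_replicas + 1)
    replicas = draw_with_replacement(images, n_replicas,
                                    np.random.default_rng(draw_seed))
    values: dict[str, list[float]] = {}
    n_failed = 0
    errors: list[str] = []
    for replica, rseed in zip(replicas, replica_seeds):
        try:
            result = pipeline(replica, int(rseed.generate_state(1)[0]))
        except Exception as exc:  # noqa: BLE001 - replica failures are data
            n_failed += 1
            errors.append(f"{type(exc).__name__}: {exc}")
            continue
        for name, value in result.items():
            if value is not None:
                values.setdefault(name, []).append(float(value))
    if n_failed > n_replicas / 2:
        raise RuntimeError(
            f"{n_failed}/{n_replicas} bootstrap replicas failed; first "
            f"errors: {errors[:3]}"
        )
    parameters = {}
    for name, vals in values.items():
        arr = np.array(vals)
        parameters[name] = ParameterStat(
            mean=float(arr.mean()),
            sd=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
            n_replicas=len(arr),
            replica_values=arr,
        )
    return BootstrapResult(parameters, n_failed)


def combine_gaussians(
    components: Sequence[tuple[float, float]], check: bool = True
) -> MixtureSummary:
    """Summary of an equal-weight sum of Gaussian distributions.

    Closed form: overall mean is the mean of component means and the
    overall variance is ``mean(sd_i² + mean_i²) − overall_mean²``.  With
    ``check=True`` the result is cross-validated against direct numerical
    summation of the component densities on a grid.
    """
    comps = [(float(m), float(s)) for m, s in components]
    if not comps:
        raise ValueError("need at least one component")
    if any(s <= 0 for _, s in comps):
        raise ValueError("component sds must be positive")
    means = np.array([m for m, _ in comps])
    sds = np.array([s for _, s in comps])
    overall_mean = float(means.mean())
    overall_var = float(np.mean(sds**2 + means**2) - overall_mean**2)
    overall_sd = float(np.sqrt(max(overall_var, 0.0)))

    if check:
        lo = (means - 10 * sds).min()
        hi = (means + 10 * sds).max()
        x = np.linspace(lo, hi, 20001)
        pdf = np.mean([sps.norm.pdf(x, m, s) for m, s in comps], axis=0)
        w = pdf / np.trapezoid(pdf, x)
        num_mean = np.trapezoid(x * w, x)
        num_sd = np.sqrt(np.trapezoid((x - num_mean) ** 2 * w, x))
        scale = max(abs(overall_sd), 1e-12)
        if abs(num_sd - overall_sd) / scale > 1e-4:
            warnings.warn(
                f"mixture closed form ({overall_sd:.6g}) and grid summation "
                f"({num_sd:.6g}) disagree", RuntimeWarning, stacklevel=2
            )
    return MixtureSummary(comps, overall_mean, overall_sd)


def welch_test(
    summary1: tuple[float, float, int], summary2: tuple[float, float, int]
) -> WelchResult:
    """Welch's unequal-variance t-test from (mean, sd, n) summaries.

    Degrees of freedom via Welch–Satterthwaite (fractional); two-sided p
    from the t distribution.  The degenerate case of both sds zero with
    equal means returns p = 1 by convention.
    """
    m1, s1, n1 = summary1
    m2, s2, n2 = summary2
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 in each group")
    if s1 < 0 or s2 < 0:
        raise ValueError("sds must be >= 0")
    v1, v2 = s1**2 / n1, s2**2 / n2
    if v1 + v2 == 0:
        if m1 == m2:
            return WelchResult(0.0, float(n1 + n2 - 2), 1.0)
        return WelchResult(float("inf"), float(n1 + n2 - 2), 0.0)
    t = (m1 - m2) / np.sqrt(v1 + v2)
    dof = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * float(sps.t.sf(abs(t), dof))
    return WelchResult(float(t), float(dof), p)


def step_trend(
    steps: Sequence[float],
    values: Sequence[float],
    sds: Sequence[float],
) -> dict:
    """Inverse-variance-weighted linear trend of a parameter vs step size.

    Returns the weighted least-squares slope, its standard error (from the
    known per-point variances) and a two-sided p-value for slope = 0 using a
    t reference with n − 2 degrees of freedom.
    """
    x = np.asarray(steps, dtype=float)
    y = np.asarray(values, dtype=float)
    s = np.asarray(sds, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 step sizes")
    if np.all(s == 0):
        raise ValueError("all sds are zero; weights are undefined")
    if np.ptp(x) == 0:
        raise ValueError("step sizes are degenerate (all equal)")
    s = np.where(s == 0, s[s > 0].min() * 1e-3, s)  # guard isolated zeros
    w = 1.0 / s**2
    sw = w.sum()
    xbar = np.sum(w * x) / sw
    ybar = np.sum(w * y) / sw
    sxx = np.sum(w * (x - xbar) ** 2)
    slope = float(np.sum(w * (x - xbar) * (y - ybar)) / sxx)
    intercept = float(ybar - slope * xbar)
    slope_se = float(np.sqrt(1.0 / sxx))
    t = slope / slope_se
    p = 2.0 * float(sps.t.sf(abs(t), len(x) - 2))
    return {"slope": slope, "slope_se": slope_se, "intercept": intercept,
            "t": float(t), "p": p}
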