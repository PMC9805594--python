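"""Synthetic measurement generation and dataset I/O.

Noisy data are produced from a nominal simulation by additive Gaussian noise
with a mixed absolute/relative standard deviation,

    y~_ij = y_ij + (sigma_abs + sigma_rel * y_ij) * X_ij,   X_ij ~ N(0, 1),

where ``sigma_abs`` is specified as a fraction of the per-output trajectory
maximum (the convention used for "2% absolute noise" on signals whose scale
varies between outputs) or, optionally, as a raw value in output units.  The
per-point standard deviations are stored alongside the measurements and feed
the likelihood directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .models import ODEModel, simulate

__all__ = ["Dataset", "generate_dataset", "load_dataset", "save_dataset"]

SIGMA_FLOOR = 1e-10  # protects the log term of the likelihood


@dataclass(frozen=True)
class Dataset:
    """Measurement table: times, values and per-point standard deviations."""

    times: np.ndarray  # (t_f,)
    y: np.ndarray  # (t_f, n_y)
    sigma: np.ndarray  # (t_f, n_y)
    output_names: tuple[str, ...] = ()
    noise_spec: dict = field(default_factory=dict)  # generation record, if synthetic

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "y", np.atleast_2d(np.asarray(self.y, dtype=float)))
        object.__setattr__(self, "sigma", np.atleast_2d(np.asarray(self.sigma, dtype=float)))
        if self.y.shape != self.sigma.shape or self.y.shape[0] != self.times.size:
            raise ValueError("times, y and sigma shapes are inconsistent")
        if not self.output_names:
            object.__setattr__(
                self, "output_names", tuple(f"y{j + 1}" for j in range(self.y.shape[1]))
            )

    @property
    def n_points(self) -> int:
        return self.times.size

    @property
    def n_outputs(self) -> int:
        return self.y.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = {"time": self.times}
        for j, name in enumerate(self.output_names):
            cols[name] = self.y[:, j]
            cols[f"{name}_sd"] = self.sigma[:, j]
        return pd.DataFrame(cols)


def scaled_sigma_abs(outputs: np.ndarray, sigma_abs: float, mode: str) -> np.ndarray:
    """Per-output absolute noise term: fraction of max |y| or raw units."""
    if mode == "fraction_of_max":
        return sigma_abs * np.max(np.abs(outputs), axis=0)
    if mode == "absolute":
        return np.full(outputs.shape[1], float(sigma_abs))
    raise ValueError(f"unknown sigma_abs mode {mode!r}")


def generate_dataset(
    model: ODEModel,
    theta: np.ndarray | None = None,
    times: np.ndarray | None = None,
    sigma_abs: float = 0.02,
    sigma_rel: float = 0.02,
    seed: int = 0,
    inputs=None,
    w=None,
    x0: np.ndarray | None = None,
    sigma_abs_mode: str = "fraction_of_max",
) -> Dataset:
    """Simulate the model at nominal/truth values and add Gaussian noise.

    Reproducible for a fixed ``seed``.  Negative standard deviations (possible
    for negative outputs with relative noise) are floored with a warning.
    """
    if sigma_abs < 0 or sigma_rel < 0:
        raise ValueError("noise levels must be non-negative")
    traj = simulate(model, theta=theta, x0=x0, times=times, inputs=inputs, w=w)
    y_true = traj.outputs
    abs_term = scaled_sigma_abs(y_true, sigma_abs, sigma_abs_mode)
    sigma = abs_term[None, :] + sigma_rel * y_true
    if np.any(sigma < 0):
        warnings.warn("negative noise standard deviations floored", RuntimeWarning)
    sigma_floored = np.maximum(sigma, SIGMA_FLOOR)
    rng = np.random.default_rng(seed)
    noise = sigma * rng.standard_normal(y_true.shape)
    if sigma_abs == 0 and sigma_rel == 0:
        noise = np.zeros_like(y_true)
    return Dataset(
        times=np.asarray(times, dtype=float),
        y=y_true + noise,
        sigma=sigma_floored,
        noise_spec={
            "sigma_abs": float(sigma_abs),
            "sigma_rel": float(sigma_rel),
            "sigma_abs_mode": sigma_abs_mode,
            "sigma_abs_scaled": [float(v) for v in abs_term],
            "seed": int(seed),
        },
    )


def save_dataset(dataset: Dataset, path) -> None:
    """CSV with columns time,<output>,<output>_sd plus a YAML sidecar."""
    dataset.to_frame().to_csv(path, index=False)
    if dataset.noise_spec:
        with open(str(path) + ".meta.yaml", "w") as fh:
            yaml.safe_dump(dataset.noise_spec, fh)


def load_dataset(path) -> Dataset:
    df = pd.read_csv(path)
    names = [c for c in df.columns if c != "time" and not c.endswith("_sd")]
    y = df[names].to_numpy()
    sigma = df[[f"{n}_sd" for n in names]].to_numpy()
    return Dataset(times=df["time"].to_numpy(), y=y, sigma=sigma, output_names=tuple(names))
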