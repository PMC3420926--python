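"""Empirical cell-death tolerance surfaces and voxel damage fields.

Injury is quantified by the damage parameter D, the percent area of cell
death predicted by culture-derived tolerance criteria as a function of
local axonal strain (dimensionless), effective strain rate (1/s) and time
from insult (days, validated up to 4 days / 96 h). The surfaces are
monotone non-decreasing in time — cellular repair and regeneration are not
modeled — and only non-negative strain and strain rate contribute
(negative values are clamped to zero before evaluation). Cortical death is
strain-rate dependent; hippocampal death is not, and the more conservative
hippocampal form is applied to the entire hippocampus.

Coefficients live in a versioned YAML registry (``data/death_params.yaml``)
rather than code, so that region-specific criteria can be substituted as
they become available.

D is evaluated per increment on the (strain, strain-rate) pair *jointly* —
the maximum of D over increments is used, never D(max strain, max rate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

logger = logging.getLogger(__name__)

#: validity horizon of the tolerance surfaces (days post-insult)
T_VALID_DAYS = 4.0
#: default critical cell-death threshold (percent) above which a voxel is damaged
D_CRIT_DEFAULT = 3.0
#: classic axonal-strain threshold for degraded electrophysiological function
STRAIN_THRESHOLD_DEFAULT = 0.18


@dataclass(frozen=True)
class DeathParams:
    """Coefficients of one region's tolerance surface D(t, eps, epsdot)."""

    region_kind: str
    amplitude: float
    time_exponent: float
    strain_exponent: float
    rate_exponent: float = 0.0
    rate_dependent: bool = False

    def __post_init__(self):
        if self.amplitude < 0 or self.time_exponent < 0 or self.strain_exponent < 0:
            raise ValueError("tolerance-surface coefficients must be non-negative")
        if self.rate_dependent and self.rate_exponent <= 0:
            raise ValueError("rate-dependent surface needs a positive rate exponent")


class DeathParamRegistry:
    """Region kind -> tolerance surface, loaded from a YAML registry."""

    def __init__(self, regions: dict[str, DeathParams], aliases: dict[str, str] | None = None,
                 version: int = 0):
        self._regions = dict(regions)
        self._aliases = dict(aliases or {})
        self.version = version
        for alias, target in self._aliases.items():
            if target not in self._regions:
                raise ValueError(f"alias {alias!r} points at unknown region {target!r}")

    @classmethod
    def from_yaml(cls, path=None) -> "DeathParamRegistry":
        if path is None:
            text = resources.files("traumaconn").joinpath("data/death_params.yaml").read_text()
        else:
            with open(path) as fh:
                text = fh.read()
        doc = yaml.safe_load(text)
        regions = {}
        for name, spec in doc["regions"].items():
            if spec.get("form", "power_law") != "power_law":
                raise ValueError(f"unknown tolerance-surface form {spec.get('form')!r}")
            regions[name] = DeathParams(
                region_kind=name,
                amplitude=float(spec["amplitude"]),
                time_exponent=float(spec["time_exponent"]),
                strain_exponent=float(spec["strain_exponent"]),
                rate_exponent=float(spec.get("rate_exponent", 0.0)),
                rate_dependent=bool(spec.get("rate_dependent", False)),
            )
        return cls(regions, doc.get("aliases"), version=int(doc.get("version", 0)))

    @property
    def kinds(self) -> list[str]:
        return sorted(set(self._regions) | set(self._aliases))

    def get(self, region_kind: str) -> DeathParams:
        name = self._aliases.get(region_kind, region_kind)
        try:
            return self._regions[name]
        except KeyError:
            raise KeyError(
                f"unregistered region kind {region_kind!r}; registered kinds: {self.kinds}"
            ) from None


_default_registry: DeathParamRegistry | None = None


def default_registry() -> DeathParamRegistry:
    global _default_registry
    if _default_registry is None:
        _default_registry = DeathParamRegistry.from_yaml()
    return _default_registry


def cell_death(params: DeathParams, strain, strain_rate, t_days) -> np.ndarray | float:
    """Percent area of cell death D(t, eps, epsdot) for one region kind.

    Negative strain or strain rate is clamped to zero before evaluation;
    a rate-independent region ignores the strain rate entirely. Times past
    the 4-day validation horizon are allowed with a warning.
    """
    strain = np.asarray(strain, dtype=float)
    strain_rate = np.asarray(strain_rate, dtype=float)
    t = np.asarray(t_days, dtype=float)
    if not (np.all(np.isfinite(strain)) and np.all(np.isfinite(strain_rate))
            and np.all(np.isfinite(t))):
        raise ValueError("strain, strain rate and time must be finite")
    if np.any(t < 0):
        raise ValueError("time from insult must be non-negative")
    if np.any(t > T_VALID_DAYS):
        logger.warning(
            "evaluating cell death at t > %g days: the tolerance surfaces are "
            "not validated beyond 96 h", T_VALID_DAYS,
        )
    eps = np.clip(strain, 0.0, None)
    d = params.amplitude * t**params.time_exponent * eps**params.strain_exponent
    if params.rate_dependent:
        d = d * np.clip(strain_rate, 0.0, None) ** params.rate_exponent
    return d if d.ndim else float(d)


def max_cell_death_over_increments(params: DeathParams, history, voxel, t_days) -> float:
    """Max over increments of D evaluated on each (strain, rate) pair jointly.

    The joint evaluation matters: the maximizing increment need not carry
    either the maximum strain or the maximum strain rate.
    """
    voxel = tuple(int(v) for v in np.asarray(voxel).reshape(3))
    eps = history.strain[voxel]
    rate = history.strain_rate[voxel]
    if len(eps) == 0:
        raise ValueError("empty strain history")
    return float(np.max(cell_death(params, eps, rate, t_days)))


@dataclass
class DamageField:
    """Per-voxel percent cell death at one post-impact time, with its mask.

    ``mask`` is True exactly where D strictly exceeds ``D_crit``.
    """

    t_post: float  # days
    D: np.ndarray  # percent cell death, >= 0
    D_crit: float = D_CRIT_DEFAULT
    mask: np.ndarray = None

    def __post_init__(self):
        self.D = np.asarray(self.D, dtype=float)
        if np.any(self.D < 0) or not np.all(np.isfinite(self.D)):
            raise ValueError("D must be finite and non-negative")
        expected = self.D > self.D_crit
        if self.mask is None:
            self.mask = expected
        elif not np.array_equal(np.asarray(self.mask, dtype=bool), expected):
            raise ValueError("mask must equal D > D_crit")

    @property
    def n_damaged(self) -> int:
        return int(self.mask.sum())


def damage_field(
    region_kinds: np.ndarray,
    history,
    t_days: float,
    D_crit: float = D_CRIT_DEFAULT,
    registry: DeathParamRegistry | None = None,
) -> DamageField:
    """Voxel-wise maximum cell death over increments, thresholded at D_crit.

    Parameters
    ----------
    region_kinds : object/str array, shape = grid
        Per-voxel region kind; empty string (or None) marks background
        voxels, which receive D = 0.
    """
    registry = registry or default_registry()
    region_kinds = np.asarray(region_kinds, dtype=object)
    if region_kinds.shape != history.grid_shape:
        raise ValueError(
            f"region_kinds shape {region_kinds.shape} does not match "
            f"history grid {history.grid_shape}"
        )
    D = np.zeros(history.grid_shape, dtype=float)
    for kind in {k for k in region_kinds.ravel() if k}:
        params = registry.get(str(kind))
        sel = region_kinds == kind
        d = cell_death(params, history.strain[sel], history.strain_rate[sel], t_days)
        D[sel] = np.max(np.atleast_2d(d), axis=-1)
    return DamageField(t_post=float(t_days), D=D, D_crit=float(D_crit))


def strain_threshold_mask(history, threshold: float = STRAIN_THRESHOLD_DEFAULT) -> np.ndarray:
    """Alternative purely mechanical criterion: voxels whose max-over-increments
    axonal strain strictly exceeds ``threshold`` (default 18%)."""
    return np.max(history.strain, axis=-1) > threshold
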