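"""Synthetic fixtures: known-dimension fractal images, pseudo-trabecular
textures, and simulated cohorts.

The cohort simulator is parameterized, by default, with the published
per-cell design of the study population this package targets: 110
temporomandibular-disorder (TMD) patients and 110 age-group-matched
controls, stratified into four age bands and two genders, with per-cell
means and standard deviations of the left- and right-condyle fractal
dimensions (LC_FD, RC_FD).  Per-subject (LC, RC) pairs are drawn from a
bivariate normal with configurable within-subject correlation,
truncated to the physically meaningful range (0, 2].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

__all__ = [
    "AGE_GROUPS",
    "AGE_BANDS",
    "CellSpec",
    "CohortParams",
    "OVERALL_LC_FD",
    "default_cohort_params",
    "make_sierpinski_carpet",
    "make_line",
    "make_filled_rect",
    "make_trabecular_texture",
    "simulate_cohort",
    "overall_weighted_mean",
]

AGE_GROUPS = ("18-29", "30-39", "40-49", "50+")

#: Inclusive age range of each band; the study enrolled ages 18-75.
AGE_BANDS = {"18-29": (18, 29), "30-39": (30, 39), "40-49": (40, 49), "50+": (50, 75)}


@dataclass(frozen=True)
class CellSpec:
    """One design cell: subject count and FD moments for both condyles."""

    n: int
    lc_mean: float
    lc_sd: float
    rc_mean: float
    rc_sd: float

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError(f"cell n must be >= 0, got {self.n}")
        if self.lc_sd <= 0 or self.rc_sd <= 0:
            raise ValueError("cell SDs must be > 0")


# Published descriptive statistics, keyed (group, age_group, gender).
# Patient cells.
_PATIENT_CELLS = {
    ("patient", "18-29", "male"): CellSpec(12, 1.2539, 0.0909, 1.2675, 0.0858),
    ("patient", "18-29", "female"): CellSpec(12, 1.1857, 0.1066, 1.2367, 0.0914),
    ("patient", "30-39", "male"): CellSpec(7, 1.2510, 0.0511, 1.2520, 0.0674),
    ("patient", "30-39", "female"): CellSpec(26, 1.2339, 0.0758, 1.2406, 0.0821),
    ("patient", "40-49", "male"): CellSpec(13, 1.2254, 0.0911, 1.1820, 0.0986),
    ("patient", "40-49", "female"): CellSpec(13, 1.2122, 0.0722, 1.1920, 0.0788),
    ("patient", "50+", "male"): CellSpec(15, 1.2150, 0.0934, 1.2392, 0.0682),
    ("patient", "50+", "female"): CellSpec(12, 1.2103, 0.0700, 1.1938, 0.0852),
}
# Control cells (gender counts follow the left-condyle rows of the
# published descriptives; the right-condyle rows print different counts,
# an inconsistency the simulator cannot honour with one row per subject).
_CONTROL_CELLS = {
    ("control", "18-29", "male"): CellSpec(13, 1.3008, 0.0645, 1.2412, 0.1455),
    ("control", "18-29", "female"): CellSpec(11, 1.3462, 0.0434, 1.3004, 0.1103),
    ("control", "30-39", "male"): CellSpec(12, 1.2893, 0.0847, 1.2392, 0.0958),
    ("control", "30-39", "female"): CellSpec(21, 1.3028, 0.0860, 1.3095, 0.0963),
    ("control", "40-49", "male"): CellSpec(14, 1.2899, 0.0730, 1.3212, 0.1025),
    ("control", "40-49", "female"): CellSpec(12, 1.2850, 0.0830, 1.3265, 0.0727),
    ("control", "50+", "male"): CellSpec(15, 1.2497, 0.0562, 1.2669, 0.0757),
    ("control", "50+", "female"): CellSpec(12, 1.3007, 0.0634, 1.2361, 0.1106),
}

DEFAULT_CELLS = {**_PATIENT_CELLS, **_CONTROL_CELLS}

#: Published whole-age-band ("overall population") left-condyle FD
#: moments, keyed (group, age_group) -> (n, mean, sd).  Their
#: sample-size-weighted means are the study's overall per-group FDs.
OVERALL_LC_FD = {
    ("patient", "18-29"): (24, 1.2198, 0.1030),
    ("patient", "30-39"): (33, 1.2376, 0.0709),
    ("patient", "40-49"): (26, 1.2188, 0.0808),
    ("patient", "50+"): (27, 1.2129, 0.0823),
    ("control", "18-29"): (24, 1.3216, 0.0594),
    ("control", "30-39"): (33, 1.2979, 0.0844),
    ("control", "40-49"): (26, 1.2877, 0.0762),
    ("control", "50+"): (27, 1.2724, 0.0638),
}


@dataclass(frozen=True)
class CohortParams:
    """Full simulation design: per-cell moments plus LC/RC correlation."""

    cells: dict = field(default_factory=lambda: dict(DEFAULT_CELLS))
    rho: float = 0.5

    def __post_init__(self) -> None:
        if not -1.0 < self.rho < 1.0:
            raise ValueError(f"rho must be in (-1, 1), got {self.rho}")

    def scaled_sds(self, factor: float) -> "CohortParams":
        """Return a copy with every SD multiplied by ``factor``."""
        cells = {
            k: replace(c, lc_sd=c.lc_sd * factor, rc_sd=c.rc_sd * factor)
            for k, c in self.cells.items()
        }
        return CohortParams(cells=cells, rho=self.rho)

    def with_n(self, n: int) -> "CohortParams":
        """Return a copy with every cell's subject count set to ``n``."""
        cells = {k: replace(c, n=n) for k, c in self.cells.items()}
        return CohortParams(cells=cells, rho=self.rho)


def default_cohort_params() -> CohortParams:
    return CohortParams()


def zero_separation_params(rho: float = 0.5) -> CohortParams:
    """The default design with all group separation removed.

    Patient cells keep their subject counts but take the matching
    control cell's FD moments, so patient and control FD distributions
    are identical — the null design for classifier and test calibration.
    """
    cells = {}
    for (group, age_group, gender), cell in DEFAULT_CELLS.items():
        ctrl = DEFAULT_CELLS[("control", age_group, gender)]
        cells[(group, age_group, gender)] = replace(ctrl, n=cell.n)
    return CohortParams(cells=cells, rho=rho)


def overall_weighted_mean(group: str, convention: str = "left") -> float:
    """Sample-size-weighted mean FD over the group's age-band cells.

    ``convention`` selects which condyle(s) enter the average: "left"
    (the left-condyle whole-band means, which is how the published
    overall group means of 1.2232 / 1.2944 arise) or "both" (average of
    the left- and right-condyle band means).
    """
    if convention == "left":
        cells = [(n, m) for (g, _), (n, m, _) in OVERALL_LC_FD.items() if g == group]
    elif convention == "both":
        cells = []
        for age in AGE_GROUPS:
            n, lc_m, _ = OVERALL_LC_FD[(group, age)]
            sub = [c for (g, a, _), c in DEFAULT_CELLS.items() if g == group and a == age]
            rc_m = sum(c.n * c.rc_mean for c in sub) / sum(c.n for c in sub)
            cells.append((n, 0.5 * (lc_m + rc_m)))
    else:
        raise ValueError(f"unknown convention {convention!r}")
    total = sum(n for n, _ in cells)
    return sum(n * m for n, m in cells) / total


# ---------------------------------------------------------------------------
# Deterministic fractal fixtures


def make_sierpinski_carpet(depth: int) -> np.ndarray:
    """3^depth x 3^depth Sierpinski carpet; foreground count is 8^depth.

    The carpet's box-counting dimension is log 8 / log 3 ~ 1.8928, which
    makes it the canonical validation fixture for the FD estimator.
    """
    if not 1 <= depth <= 6:
        raise ValueError(f"depth must be in [1, 6], got {depth}")
    cell = np.ones((3, 3), dtype=bool)
    cell[1, 1] = False
    carpet = np.ones((1, 1), dtype=bool)
    for _ in range(depth):
        carpet = np.kron(carpet, cell)
    return carpet


def make_line(length: int, orientation: str = "horizontal") -> np.ndarray:
    """A 1-pixel-wide line across the middle of a length x length image."""
    if length < 1:
        raise ValueError("length must be positive")
    img = np.zeros((length, length), dtype=bool)
    mid = length // 2
    if orientation == "horizontal":
        img[mid, :] = True
    elif orientation == "vertical":
        img[:, mid] = True
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return img


def make_filled_rect(width: int, height: int) -> np.ndarray:
    """A fully foreground height x width mask (dimension-2 fixture)."""
    if width < 1 or height < 1:
        raise ValueError("dimensions must be positive")
    return np.ones((height, width), dtype=bool)


def make_trabecular_texture(size: int = 128, complexity: float = 0.5, seed: int = 0) -> np.ndarray:
    """Band-pass-filtered noise emulating trabecular radiograph texture.

    ``complexity`` in [0, 1] sets the dominant feature scale: 0 gives
    coarse, blobby structure (low spatial frequency, low FD after the
    preprocessing chain) and 1 gives fine, dense structure (high
    frequency, high FD).  Deterministic per seed; output spans the full
    8-bit range.
    """
    if size < 64:
        raise ValueError(f"size must be >= 64, got {size}")
    if not 0.0 <= complexity <= 1.0:
        raise ValueError(f"complexity must be in [0, 1], got {complexity}")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((size, size))
    # Feature scale shrinks from 8 px to 1 px as complexity rises; the
    # wider blur removes frequencies below the band of interest.
    sigma_hi = 8.0 - 7.0 * complexity
    sigma_lo = 4.0 * sigma_hi
    band = ndi.gaussian_filter(noise, sigma_hi, mode="reflect") - ndi.gaussian_filter(
        noise, sigma_lo, mode="reflect"
    )
    lo, hi = band.min(), band.max()
    return np.clip(np.rint((band - lo) * (255.0 / (hi - lo))), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Cohort simulation


def _draw_truncated_bivariate(
    rng: np.random.Generator,
    n: int,
    mean: np.ndarray,
    cov: np.ndarray,
) -> np.ndarray:
    """n draws from N(mean, cov) rejected outside (0, 2] per coordinate."""
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        draw = rng.multivariate_normal(mean, cov, size=n - filled, method="cholesky")
        ok = np.all((draw > 0.0) & (draw <= 2.0), axis=1)
        kept = draw[ok]
        out[filled : filled + len(kept)] = kept
        filled += len(kept)
    return out


def simulate_cohort(params: CohortParams | None = None, seed: int = 42) -> pd.DataFrame:
    """Simulate one cohort table (one row per subject).

    Columns: subject_id, age, gender, group, lc_fd, rc_fd.  Ages are
    drawn uniformly within each band; (lc_fd, rc_fd) jointly normal at
    the cell's moments with correlation ``params.rho``, truncated to
    (0, 2].  Deterministic per seed.
    """
    params = params or CohortParams()
    rng = np.random.default_rng(seed)
    rows = []
    counters = {"patient": 0, "control": 0}
    for (group, age_group, gender), cell in sorted(params.cells.items()):
        if cell.n == 0:
            continue
        lo, hi = AGE_BANDS[age_group]
        ages = rng.integers(lo, hi + 1, size=cell.n)
        cov = np.array(
            [
                [cell.lc_sd**2, params.rho * cell.lc_sd * cell.rc_sd],
                [params.rho * cell.lc_sd * cell.rc_sd, cell.rc_sd**2],
            ]
        )
        fds = _draw_truncated_bivariate(
            rng, cell.n, np.array([cell.lc_mean, cell.rc_mean]), cov
        )
        prefix = "P" if group == "patient" else "C"
        for i in range(cell.n):
            counters[group] += 1
            rows.append(
                {
                    "subject_id": f"{prefix}{counters[group]:03d}",
                    "age": int(ages[i]),
                    "gender": gender,
                    "group": group,
                    "lc_fd": float(fds[i, 0]),
                    "rc_fd": float(fds[i, 1]),
                }
            )
    return pd.DataFrame(rows, columns=["subject_id", "age", "gender", "group", "lc_fd", "rc_fd"])
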