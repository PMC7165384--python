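"""Synthetic childhood-cancer registry generator.

The real study population (a national childhood-cancer registry joined
to census person-time on a 1 km² grid) is confidential, so every
analysis stage here is exercised on synthetic data that reproduce its
statistical structure: three age groups (0–4, 5–9, 10–15), diagnosis
years 1985–2015, censuses in 1990, 2000 and 2010–2015 with linear
interpolation in between, roughly 6000 cases in total, smooth continuous
covariate surfaces scaled to unit SD, and categorical surfaces for
language region (3 levels) and urbanisation (3 levels).

The generators draw a latent Gaussian risk field and realise case
locations from an inhomogeneous Poisson process with intensity
E(s)·r(s), which is exactly the data-generating model the fitting code
assumes — so parameter-recovery and coverage tests are well defined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import box, mapping, shape as shapely_shape

from . import spdecore
from ._linalg import Chol

__all__ = [
    "GridSpec",
    "ScenarioConfig",
    "PopulationPanel",
    "CovariateSet",
    "ExpectedSurface",
    "CaseSet",
    "ScenarioData",
    "square_window",
    "simulate_population",
    "simulate_covariates",
    "sample_gaussian_field",
    "simulate_cases",
    "simulate_scenario",
]

AGE_GROUPS_DEFAULT = ("0-4", "5-9", "10-15")
ERROR_CLASS_PROBS = (0.70, 0.24, 0.05, 0.01)  # 94% within classes 1-2 (< 100 m)


def square_window(size_km: float):
    """Square observation window [0, size] x [0, size] in km."""
    return box(0.0, 0.0, float(size_km), float(size_km))


@dataclass
class GridSpec:
    """Regular grid of square cells tiling the observation window.

    Cells are indexed k = 0..K-1 in row-major order over the window's
    bounding box; only cells whose centroid falls inside the window are
    kept (for rectangular windows that is all of them).
    """

    window: object  # shapely polygon, km units
    cell_size: float = 1.0

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        xmin, ymin, xmax, ymax = self.window.bounds
        h = self.cell_size
        nx = max(int(np.round((xmax - xmin) / h)), 1)
        ny = max(int(np.round((ymax - ymin) / h)), 1)
        xs = xmin + h * (np.arange(nx) + 0.5)
        ys = ymin + h * (np.arange(ny) + 0.5)
        X, Y = np.meshgrid(xs, ys)
        cent = np.column_stack([X.ravel(), Y.ravel()])
        if self.window.area < (xmax - xmin) * (ymax - ymin) - 1e-9:
            from shapely import points as shapely_points
            keep = self.window.covers(shapely_points(cent))
            cent = cent[np.asarray(keep, dtype=bool)]
        if cent.shape[0] == 0:
            raise ValueError("grid has no cells inside the window")
        self.centroids = cent
        self.nx, self.ny = nx, ny

    @property
    def n_cells(self) -> int:
        return self.centroids.shape[0]

    @property
    def bounds(self):
        return self.window.bounds

    def window_to_geojson(self, path: str | Path) -> None:
        gj = {"type": "Feature", "properties": {}, "geometry": mapping(self.window)}
        Path(path).write_text(json.dumps(gj))

    @classmethod
    def from_geojson(cls, path: str | Path, cell_size: float = 1.0) -> "GridSpec":
        gj = json.loads(Path(path).read_text())
        geom = gj["geometry"] if gj.get("type") == "Feature" else gj
        return cls(window=shapely_shape(geom), cell_size=cell_size)


@dataclass
class ScenarioConfig:
    """Everything the generators need to emulate the study.

    covariate_sds are the raw-unit SDs of the continuous surrogates; the
    NO2 value is stored with its printed unit label verbatim (the label
    is metadata and is never interpreted — the design matrix is SD-scaled
    either way).  true_beta are log relative risks per SD (continuous)
    or per level (categorical indicators).
    """

    age_groups: tuple = AGE_GROUPS_DEFAULT
    years: tuple[int, int] = (1985, 2015)
    census_years: tuple = (1990, 2000, 2010, 2011, 2012, 2013, 2014, 2015)
    target_total_cases: int = 5947
    national_population: float = 1_300_000.0
    covariate_sds: dict = dc_field(default_factory=lambda: {
        "no2": 77.7,
        "radiation": 60.2,
        "sep": 8.7,
        "registry_years": 11.6,
    })
    covariate_units: dict = dc_field(default_factory=lambda: {
        "no2": "μg/m^3 × 10 (verbatim)",
        "radiation": "nSv/h",
        "sep": "SEP units",
        "registry_years": "years",
    })
    true_beta: dict = dc_field(default_factory=lambda: {
        "no2": np.log(1.02),
        "radiation": np.log(1.17),
        "sep": np.log(1.06),
        "registry_years": np.log(1.06),
        "lang:French": np.log(1.18),
        "lang:Italian": np.log(1.05),
        "urban:semi-urban": np.log(0.97),
        "urban:urban": np.log(1.05),
    })
    true_sigma: float = 0.15
    true_rho: float = 50.0
    infant_fraction: float = 0.19  # share of the 0-4 stratum aged < 1 year
    seed: int = 0

    def __post_init__(self):
        if any(sd <= 0 for sd in self.covariate_sds.values()):
            raise ValueError("all covariate SDs must be positive")
        y0, y1 = self.years
        if any(not (y0 <= c <= y1) for c in self.census_years):
            raise ValueError("census_years must lie within years")
        if self.target_total_cases <= 0:
            raise ValueError("target_total_cases must be positive")
        if self.true_sigma <= 0 or self.true_rho <= 0:
            raise ValueError("field hyperparameters must be positive")

    @property
    def year_list(self) -> np.ndarray:
        return np.arange(self.years[0], self.years[1] + 1)

    def to_yaml(self, path: str | Path) -> None:
        d = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        d["true_beta"] = {k: float(v) for k, v in self.true_beta.items()}
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("age_groups", "census_years", "years"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class PopulationPanel:
    """Person-years P_ijk indexed by (age group i, year j, cell k)."""

    counts: np.ndarray  # (I, J, K), non-negative
    age_groups: tuple
    years: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 3:
            raise ValueError("counts must be (age, year, cell)")
        if np.any(self.counts < 0):
            raise ValueError("population counts must be non-negative")
        if self.counts.shape[:2] != (len(self.age_groups), len(self.years)):
            raise ValueError("counts shape inconsistent with labels")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[2]

    def restrict_years(self, years) -> "PopulationPanel":
        years = np.asarray(years)
        idx = [int(np.where(self.years == y)[0][0]) for y in years]
        return PopulationPanel(self.counts[:, idx, :], self.age_groups, years)

    def to_csv(self, path: str | Path) -> None:
        I, J, K = self.counts.shape
        i, j, k = np.meshgrid(np.arange(I), np.arange(J), np.arange(K),
                              indexing="ij")
        pd.DataFrame({
            "age_group": np.asarray(self.age_groups)[i.ravel()],
            "year": self.years[j.ravel()],
            "k": k.ravel(),
            "count": self.counts.ravel(),
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PopulationPanel":
        df = pd.read_csv(path)
        ages = list(dict.fromkeys(df["age_group"]))
        years = np.sort(df["year"].unique())
        K = int(df["k"].max()) + 1
        counts = np.zeros((len(ages), len(years), K))
        ai = {a: i for i, a in enumerate(ages)}
        yi = {y: j for j, y in enumerate(years)}
        counts[
            df["age_group"].map(ai), df["year"].map(yi), df["k"]
        ] = df["count"].to_numpy()
        return cls(counts, tuple(ages), years)


@dataclass
class CovariateSet:
    """Design matrix over grid cells plus per-column metadata.

    ``design`` holds one row per cell: an intercept, the SD-scaled
    continuous covariates and reference-coded indicators.  ``raw``
    retains the unscaled continuous surfaces so the raw-unit SDs are
    recoverable.
    """

    design: np.ndarray  # (K, p)
    columns: list
    meta: dict          # per-column: {"type", "reference", "raw_sd", "unit"}
    raw: dict = dc_field(default_factory=dict)  # raw-unit continuous surfaces

    def __post_init__(self):
        if self.design.shape[1] != len(self.columns):
            raise ValueError("design/columns mismatch")
        if self.columns.count("intercept") != 1:
            raise ValueError("exactly one intercept column required")

    @property
    def n_cells(self) -> int:
        return self.design.shape[0]

    def subset(self, names) -> "CovariateSet":
        """Columns restricted to intercept + the named covariate blocks."""
        keep = [c for c in self.columns
                if c == "intercept" or any(
                    c == n or c.startswith(n + ":") for n in names)]
        idx = [self.columns.index(c) for c in keep]
        return CovariateSet(
            self.design[:, idx], keep,
            {c: self.meta[c] for c in keep},
            {k: v for k, v in self.raw.items() if k in names},
        )

    def intercept_only(self) -> "CovariateSet":
        return self.subset([])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.design, columns=self.columns).to_csv(
            path, index_label="k"
        )


@dataclass
class ExpectedSurface:
    """Indirectly standardised expected counts E_k per spatial unit."""

    E: np.ndarray
    unit_kind: str = "grid"        # grid | area
    analysis: str = "diagnosis"    # diagnosis | birth

    def __post_init__(self):
        self.E = np.asarray(self.E, dtype=float)
        if np.any(self.E < 0):
            raise ValueError("expected counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.E.sum())

    def to_csv(self, path: str | Path, centroids: np.ndarray | None = None) -> None:
        df = pd.DataFrame({"k": np.arange(self.E.size), "E": self.E})
        if centroids is not None:
            df.insert(1, "x_km", centroids[:, 0])
            df.insert(2, "y_km", centroids[:, 1])
        df.to_csv(path, index=False)


class CaseSet:
    """Point-referenced cancer cases: location, age group, year, group, error class."""

    COLUMNS = ["x_km", "y_km", "age_group", "year", "group", "error_class"]

    def __init__(self, records: pd.DataFrame) -> None:
        missing = set(self.COLUMNS) - set(records.columns)
        if missing:
            raise ValueError(f"case table missing columns {sorted(missing)}")
        if len(records) and not records["error_class"].isin([1, 2, 3, 4]).all():
            raise ValueError("error_class must be in 1..4")
        self.records = records.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def coords(self) -> np.ndarray:
        return self.records[["x_km", "y_km"]].to_numpy(dtype=float)

    def counts_per_cell(self, grid: GridSpec) -> np.ndarray:
        """Bin case locations to grid cells (row-major centroid order)."""
        xmin, ymin, _, _ = grid.bounds
        h = grid.cell_size
        ix = np.clip(((self.coords[:, 0] - xmin) / h).astype(int), 0, grid.nx - 1)
        iy = np.clip(((self.coords[:, 1] - ymin) / h).astype(int), 0, grid.ny - 1)
        counts = np.zeros(grid.nx * grid.ny)
        np.add.at(counts, iy * grid.nx + ix, 1.0)
        if grid.n_cells != grid.nx * grid.ny:
            raise NotImplementedError("non-rectangular windows: bin via centroids")
        return counts

    def to_csv(self, path: str | Path) -> None:
        self.records[self.COLUMNS].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CaseSet":
        return cls(pd.read_csv(path))


# --------------------------------------------------------------------------
# generators
# --------------------------------------------------------------------------

def _smooth_surface(points: np.ndarray, rng: np.random.Generator,
                    n_waves: int = 8, length_scale: float = 25.0) -> np.ndarray:
    """Low-frequency random surface: a sum of random plane cosines."""
    k = rng.normal(scale=1.0 / length_scale, size=(n_waves, 2))
    phase = rng.uniform(0, 2 * np.pi, size=n_waves)
    amp = rng.normal(size=n_waves)
    return (np.cos(points @ k.T + phase) @ amp) / np.sqrt(n_waves)


def simulate_population(grid: GridSpec, cfg: ScenarioConfig,
                        rng: np.random.Generator | None = None) -> PopulationPanel:
    """Person-time panel: smooth census-year densities, interpolated between.

    Census layers put the configured national population (split across
    age groups) on a smooth exponentiated random density; intercensal
    years are filled by the standardise module's linear interpolation,
    with constant extrapolation outside the census span.
    """
    from .standardise import interpolate_population  # lazy: avoids cycle

    if grid.n_cells == 0:
        raise ValueError("grid has no cells")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    years = cfg.year_list
    census = np.asarray(sorted(cfg.census_years))
    I, K = len(cfg.age_groups), grid.n_cells
    census_counts = np.empty((I, census.size, K))
    per_group = cfg.national_population / I
    for i in range(I):
        base = _smooth_surface(grid.centroids, rng)
        for j in range(census.size):
            # slow drift of the density between censuses
            dens = np.exp(base + 0.15 * _smooth_surface(grid.centroids, rng))
            census_counts[i, j] = dens / dens.sum() * per_group
    census_panel = PopulationPanel(census_counts, cfg.age_groups, census)
    return interpolate_population(census_panel, years)


def simulate_covariates(grid: GridSpec, cfg: ScenarioConfig,
                        rng: np.random.Generator | None = None) -> CovariateSet:
    """Surrogate covariate surfaces.

    Continuous surfaces (NO2, radiation, SEP) are smooth random fields
    centred and scaled to sample SD 1; registry-years is piecewise
    constant over a canton-like partition then scaled.  Language region
    (German reference) and urbanisation (rural reference) partition the
    window into contiguous regions via nearest-seed (Voronoi) labelling.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    pts = grid.centroids
    K = pts.shape[0]
    cols = [np.ones(K)]
    names = ["intercept"]
    meta = {"intercept": {"type": "intercept"}}
    raw = {}

    extent = max(grid.bounds[2] - grid.bounds[0], grid.bounds[3] - grid.bounds[1])

    def _scale(z):
        sd = z.std()
        if sd == 0:
            raise ValueError("degenerate covariate surface")
        return (z - z.mean()) / sd

    for name in ("no2", "radiation", "sep"):
        z = _smooth_surface(pts, rng, length_scale=extent / 4)
        raw_surface = z * cfg.covariate_sds[name] / max(z.std(), 1e-12)
        raw[name] = raw_surface
        cols.append(_scale(z))
        names.append(name)
        meta[name] = {
            "type": "continuous",
            "raw_sd": float(np.std(raw_surface)),
            "unit": cfg.covariate_units.get(name, ""),
        }

    # canton-like partition for registry-years: nearest of ~8 seeds
    n_cantons = min(8, K)
    seeds = pts[rng.choice(K, size=n_cantons, replace=False)]
    canton = np.argmin(
        ((pts[:, None, :] - seeds[None, :, :]) ** 2).sum(-1), axis=1
    )
    reg_raw = rng.uniform(0, 31, size=n_cantons)[canton]
    reg_raw = reg_raw * cfg.covariate_sds["registry_years"] / max(reg_raw.std(), 1e-12)
    raw["registry_years"] = reg_raw
    cols.append(_scale(reg_raw))
    names.append("registry_years")
    meta["registry_years"] = {
        "type": "continuous",
        "raw_sd": float(np.std(reg_raw)),
        "unit": cfg.covariate_units.get("registry_years", ""),
    }

    for cov, levels, ref in (
        ("lang", ["German", "French", "Italian"], "German"),
        ("urban", ["rural", "semi-urban", "urban"], "rural"),
    ):
        if len(levels) < 2:
            raise ValueError(f"categorical covariate {cov} needs >= 2 levels")
        seeds = pts[rng.choice(K, size=len(levels), replace=False)]
        lab = np.argmin(((pts[:, None, :] - seeds[None, :, :]) ** 2).sum(-1), axis=1)
        for li, level in enumerate(levels):
            if level == ref:
                continue
            cols.append((lab == li).astype(float))
            names.append(f"{cov}:{level}")
            meta[f"{cov}:{level}"] = {
                "type": "indicator", "reference": ref, "covariate": cov,
            }
    return CovariateSet(np.column_stack(cols), names, meta, raw)


def sample_gaussian_field(mesh: spdecore.Mesh, sigma: float, rho: float,
                          seed_or_rng) -> np.ndarray:
    """One draw of the GMRF node weights Z ~ N(0, Q(rho, sigma)^{-1})."""
    params = spdecore.MaternParams(sigma=sigma, rho=rho)
    Q = spdecore.spde_precision(mesh, params)
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    return Chol(Q).sample(rng, n=1)[0]


def simulate_cases(expected: ExpectedSurface, rr: np.ndarray,
                   cfg: ScenarioConfig, grid: GridSpec,
                   rng: np.random.Generator | None = None,
                   panel: PopulationPanel | None = None,
                   rates: np.ndarray | None = None,
                   group: str = "all") -> CaseSet:
    """Realise cases from the inhomogeneous Poisson process E(s)·r(s).

    Cell counts are Poisson(E_k · rr_k); each case is placed uniformly
    within its cell.  (age group, year) is drawn proportional to
    q_ij · P_ijk within the cell when a panel and rate table are given,
    otherwise uniformly.  Geocode-error classes follow the registry's
    margin-of-error mix (~94% within 100 m).
    """
    rr = np.asarray(rr, dtype=float)
    if np.any(expected.E < 0):
        raise ValueError("negative expected counts")
    if np.any(rr <= 0):
        raise ValueError("relative risks must be positive")
    if expected.E.size != rr.size:
        raise ValueError("expected and rr must share the cell index")
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    counts = rng.poisson(expected.E * rr)
    n = int(counts.sum())
    cell_idx = np.repeat(np.arange(expected.E.size), counts)
    h = grid.cell_size
    xmin, ymin, _, _ = grid.bounds
    cent = grid.centroids[cell_idx]
    xy = cent + rng.uniform(-h / 2, h / 2, size=(n, 2))

    years = cfg.year_list
    ages = np.asarray(cfg.age_groups if panel is None else panel.age_groups)
    I, J = len(ages), len(years)
    age_out = np.empty(n, dtype=object)
    year_out = np.empty(n, dtype=int)
    if panel is not None and rates is not None:
        w_all = rates[:, :, None] * panel.counts  # (I, J, K)
        for c in np.unique(cell_idx):
            sel = cell_idx == c
            w = w_all[:, :, c].ravel()
            tot = w.sum()
            p = w / tot if tot > 0 else np.full(I * J, 1.0 / (I * J))
            draw = rng.choice(I * J, size=sel.sum(), p=p)
            age_out[sel] = ages[draw // J]
            year_out[sel] = years[draw % J]
    else:
        draw = rng.integers(0, I * J, size=n)
        age_out[:] = ages[draw // J]
        year_out[:] = years[draw % J]
    err = rng.choice([1, 2, 3, 4], size=n, p=ERROR_CLASS_PROBS)
    return CaseSet(pd.DataFrame({
        "x_km": xy[:, 0], "y_km": xy[:, 1],
        "age_group": age_out, "year": year_out,
        "group": group, "error_class": err,
    }))


@dataclass
class ScenarioData:
    """One synthetic realisation of the study: inputs plus the truth."""

    grid: GridSpec
    cfg: ScenarioConfig
    panel: PopulationPanel
    infant_panel: PopulationPanel
    covariates: CovariateSet
    expected: ExpectedSurface
    cases: CaseSet
    birth_expected: ExpectedSurface
    birth_cases: CaseSet
    true_field: np.ndarray      # latent Z at cell centroids
    true_log_rr: np.ndarray     # X beta (centred) + Z at cells
    mesh: spdecore.Mesh


def simulate_scenario(grid: GridSpec, cfg: ScenarioConfig,
                      covariate_names: list | None = None,
                      mesh: spdecore.Mesh | None = None) -> ScenarioData:
    """Full synthetic study: population, covariates, latent risk, cases.

    The baseline incidence rate is constant over strata and set so the
    expected national total matches ``cfg.target_total_cases``; the true
    log relative risk is the centred covariate contribution plus one
    draw of the Matérn field projected to cell centroids.
    """
    rng = np.random.default_rng(cfg.seed)
    panel = simulate_population(grid, cfg, rng)
    covariates = simulate_covariates(grid, cfg, rng)
    if covariate_names is not None:
        covariates = covariates.subset(covariate_names)
    if mesh is None:
        mesh = spdecore.build_mesh(
            grid, node_spacing=max(cfg.true_rho / 5.0, grid.cell_size),
            buffer=cfg.true_rho,
        )
    z_nodes = sample_gaussian_field(mesh, cfg.true_sigma, cfg.true_rho, rng)
    A = spdecore.make_projector(mesh, grid.centroids)
    z_cells = A @ z_nodes

    beta = np.array([cfg.true_beta.get(c, 0.0) for c in covariates.columns])
    xb = covariates.design @ beta
    log_rr = (xb - xb.mean()) + z_cells

    # constant baseline rate calibrated to the national case total
    total_py = panel.counts.sum()
    q = cfg.target_total_cases / total_py
    rates = np.full(panel.counts.shape[:2], q)
    E = ExpectedSurface(q * panel.counts.sum(axis=(0, 1)), "grid", "diagnosis")

    # the RR surface is relative to the national level: normalise so the
    # person-time-weighted national mean risk is one, making the expected
    # national total equal the configured target
    rr = np.exp(log_rr)
    norm = float((E.E * rr).sum() / E.E.sum())
    rr = rr / norm
    log_rr = log_rr - np.log(norm)
    cases = simulate_cases(E, rr, cfg, grid, rng, panel=panel, rates=rates)

    # birth analysis: infants (< 1 year) as a fraction of the 0-4 stratum
    infant_counts = cfg.infant_fraction * panel.counts[:1]
    infant_panel = PopulationPanel(infant_counts, ("<1",), panel.years)
    birth_total = cfg.target_total_cases * 4198.0 / 5947.0  # registry ratio
    q0 = birth_total / infant_panel.counts.sum()
    birth_rates = np.full(infant_panel.counts.shape[:2], q0)
    E_birth = ExpectedSurface(
        q0 * infant_panel.counts.sum(axis=(0, 1)), "grid", "birth"
    )
    birth_cases = simulate_cases(
        E_birth, rr, cfg, grid, rng, panel=infant_panel, rates=birth_rates
    )
    return ScenarioData(
        grid=grid, cfg=cfg, panel=panel, infant_panel=infant_panel,
        covariates=covariates, expected=E, cases=cases,
        birth_expected=E_birth, birth_cases=birth_cases,
        true_field=z_cells, true_log_rr=log_rr, mesh=mesh,
    )
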