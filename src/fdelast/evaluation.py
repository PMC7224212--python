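"""Reconstruction error metrics: Monte-Carlo bias/precision, Cotter ranking.

``monte_carlo`` repeats noise injection + smoothing + inversion, then
summarizes the normalized maps against the normalized truth:

bias
    root-mean-square over elements of (across-replicate mean map - truth);
precision
    pooled across-replicate per-element standard deviation.

``cotter_sensitivity`` is the systematic fractional replicate two-level
design (2m+2 runs for m factors) ranking factors by the combined magnitude
of their odd- and even-order contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fem import CachedSolver
from .fields import NoiseSpec, add_noise, smooth_gaussian, smooth_lowess
from .inverse import InverseProblem, OptimizerSettings, normalize_relative_stiffness
from .phantoms import PhantomData


@dataclass
class MonteCarloResult:
    """Bias/precision summary of a replicated noisy-inversion experiment."""

    n_replicates: int
    n_failed: int
    bias: float
    precision: float
    bias_map: np.ndarray
    seeds: np.ndarray
    mean_map: np.ndarray
    sd_map: np.ndarray
    bias_per_replicate: float
    precision_replicate_rmse_sd: float
    ratios: np.ndarray | None = None

    def to_json(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        doc = {
            "n_replicates": self.n_replicates,
            "n_failed": self.n_failed,
            "bias": self.bias,
            "precision": self.precision,
            "bias_per_replicate": self.bias_per_replicate,
            "precision_replicate_rmse_sd": self.precision_replicate_rmse_sd,
            "seeds": [int(s) for s in self.seeds],
        }
        path.write_text(json.dumps(doc, indent=2))
        return path


def _smooth(field, smoothing, lowess_window, gaussian_sigma_px):
    if smoothing in (None, "none"):
        return field
    if smoothing == "lowess":
        return smooth_lowess(field, window_pixels=lowess_window)
    if smoothing == "gaussian":
        return smooth_gaussian(field, gaussian_sigma_px)
    raise ValueError(f"unknown smoothing {smoothing!r}")


def replicate_seeds(seed: int, n: int) -> np.ndarray:
    """Independent child seeds (< 2**31) from one master seed."""
    return np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64) % (2**31)


def monte_carlo(
    case: PhantomData,
    noise: NoiseSpec,
    n_replicates: int = 100,
    seed: int = 0,
    smoothing: str | None = "lowess",
    lowess_window: int = 150,
    gaussian_sigma_px: float = 2.0,
    settings: OptimizerSettings | None = None,
    ratio_labels: tuple | None = None,
) -> MonteCarloResult:
    """Monte-Carlo error analysis of the full noisy reconstruction pipeline.

    Per replicate: fresh Gaussian noise on the ideal displacements (boundary
    pixels included per ``noise.apply_to_boundary``), smoothing, inversion,
    normalization.  Non-convergent replicates are excluded and counted in
    ``n_failed``.  ``ratio_labels=(a, b)`` additionally records the region
    mean ratio a/b per replicate.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    settings = settings or OptimizerSettings()
    seeds = replicate_seeds(seed, n_replicates)
    truth = normalize_relative_stiffness(case.truth_rho, case.mesh.measures)
    # the Dirichlet pattern (all boundary nodes, all components) is identical
    # across replicates: reuse one assembly/factorization cache
    nn, dim = case.mesh.n_nodes, case.mesh.dimension
    prescribed = np.zeros(nn * dim, dtype=bool)
    for c in range(dim):
        prescribed[case.mesh.boundary_nodes * dim + c] = True
    solver = CachedSolver(case.mesh, case.spec.nu, prescribed)
    maps, ratios = [], []
    n_failed = 0
    for s in seeds:
        noisy = add_noise(case.ideal_field,
                          NoiseSpec(noise.sigma, int(s), noise.apply_to_boundary))
        smoothed = _smooth(noisy, smoothing, lowess_window, gaussian_sigma_px)
        problem = InverseProblem.from_field(
            smoothed, mesh=case.mesh, gmap=case.gmap, settings=settings,
            nu=case.spec.nu,
        )
        res = problem.fit(solver=solver)
        if not res.state.converged:
            n_failed += 1
            continue
        m = res.relative_stiffness
        maps.append(m)
        if ratio_labels is not None:
            means, _ = res.region_ratio(case.labels)
            ratios.append(means[ratio_labels[0]] / means[ratio_labels[1]])
    if len(maps) < 2:
        raise RuntimeError(f"only {len(maps)} replicates converged")
    maps = np.array(maps)
    mean_map = maps.mean(axis=0)
    sd_map = maps.std(axis=0, ddof=1)
    bias_map = mean_map - truth
    bias = float(np.sqrt(np.mean(bias_map**2)))
    precision = float(np.sqrt(np.mean(sd_map**2)))
    bias_per_rep = float(np.sqrt(np.mean((maps - truth) ** 2)))
    rep_rmse = np.sqrt(np.mean((maps - truth) ** 2, axis=1))
    return MonteCarloResult(
        n_replicates=len(maps),
        n_failed=n_failed,
        bias=bias,
        precision=precision,
        bias_map=bias_map,
        seeds=seeds,
        mean_map=mean_map,
        sd_map=sd_map,
        bias_per_replicate=bias_per_rep,
        precision_replicate_rmse_sd=float(np.std(rep_rmse, ddof=1)),
        ratios=np.array(ratios) if ratios else None,
    )


# ---------------------------------------------------------------------------
# Cotter's systematic fractional replicate design


@dataclass
class CotterDesign:
    """The 2m+2 run configurations and the per-run responses."""

    factors: list
    runs: list
    responses: np.ndarray

    def __post_init__(self):
        m = len(self.factors)
        if len(self.runs) != 2 * m + 2:
            raise ValueError("Cotter design requires exactly 2m+2 runs")


def cotter_sensitivity(factors, response) -> pd.DataFrame:
    """Rank factors by Cotter's two-level systematic fractional replicate.

    ``factors`` is a list of ``(name, low, high)``; ``response`` maps a
    ``{name: setting}`` dict to a scalar.  The 2m+2 runs are: all-low, each
    factor singly high, each factor singly low (from all-high), all-high.
    Per factor the odd/even order contrasts are

        C_o(j) = ((y_allhigh - y_{j low}) + (y_{j high} - y_alllow)) / 4
        C_e(j) = ((y_allhigh - y_{j low}) - (y_{j high} - y_alllow)) / 4

    and the importance measure is ``M(j) = |C_o(j)| + |C_e(j)|``.  Returns a
    DataFrame sorted by M (descending) with the design attached as
    ``df.attrs['design']``.
    """
    m = len(factors)
    if m < 2:
        raise ValueError("need at least two factors")
    for name, lo, hi in factors:
        if lo == hi:
            raise ValueError(f"factor {name!r} has identical low/high settings")
    names = [f[0] for f in factors]
    low = {f[0]: f[1] for f in factors}
    high = {f[0]: f[2] for f in factors}
    runs = [dict(low)]
    for name in names:
        cfg = dict(low)
        cfg[name] = high[name]
        runs.append(cfg)
    for name in names:
        cfg = dict(high)
        cfg[name] = low[name]
        runs.append(cfg)
    runs.append(dict(high))
    y = np.array([float(response(cfg)) for cfg in runs])
    rows = []
    for j, name in enumerate(names):
        d_hi = y[2 * m + 1] - y[m + 1 + j]
        d_lo = y[1 + j] - y[0]
        c_odd = (d_hi + d_lo) / 4.0
        c_even = (d_hi - d_lo) / 4.0
        rows.append((name, c_odd, c_even, abs(c_odd) + abs(c_even)))
    df = pd.DataFrame(rows, columns=["factor", "C_odd", "C_even", "M"])
    df = df.sort_values("M", ascending=False).reset_index(drop=True)
    df.attrs["design"] = CotterDesign(factors=list(factors), runs=runs, responses=y)
    return df


def default_pipeline_factors():
    """Two-level settings for the reconstruction-pipeline sensitivity study.

    noise sigma (mm), smoothing method, Poisson ratio, sensitivity-filter
    radius factor (x element size), mesh density (mm), iteration budget.
    """
    return [
        ("noise_sigma", 0.02, 0.2),
        ("smoothing", "gaussian", "lowess"),
        ("nu", 0.3, 0.49),
        ("filter_factor", 1.0, 4.0),
        ("mesh_density", 0.3, 0.6),
        ("max_iterations", 30, 100),
    ]


def pipeline_response_factory(noise_seed: int = 0, lowess_window: int = 150,
                              width: float = 6.0, height: float = 6.0):
    """Response for Cotter on the bilayer case: |recovered top:bottom - 2|.

    Each configuration rebuilds the bilayer phantom at its mesh density,
    adds noise at its sigma, smooths with its method and inverts with its
    settings; the response is the absolute error of the recovered
    top-to-bottom region-mean ratio versus the true 2.0.
    """
    from .phantoms import Bilayer, PhantomSpec, Rectangle, generate_displacements

    def response(cfg: dict) -> float:
        spec = PhantomSpec(Rectangle(width, height), Bilayer(1000.0, 500.0, 0.5),
                           resolution=cfg["mesh_density"], nu=cfg["nu"])
        case = generate_displacements(spec)
        noisy = add_noise(case.ideal_field, NoiseSpec(cfg["noise_sigma"], noise_seed))
        smoothed = _smooth(noisy, cfg["smoothing"], lowess_window, 2.0)
        settings = OptimizerSettings(
            max_iterations=int(cfg["max_iterations"]),
            filter_radius=cfg["filter_factor"] * case.mesh.typical_edge,
        )
        problem = InverseProblem.from_field(smoothed, mesh=case.mesh,
                                            gmap=case.gmap, settings=settings,
                                            nu=cfg["nu"])
        res = problem.fit()
        means, _ = res.region_ratio(case.labels)
        return abs(means[1] / means[0] - 2.0)

    return response


# ---------------------------------------------------------------------------
# reporting


def format_ratio(name_a: str, name_b: str, mean_a: float, mean_b: float) -> str:
    """Ratio string normalized so the smaller side reads 1 (e.g. '1:2.0')."""
    if mean_a <= mean_b:
        return f"{name_a}:{name_b} = 1:{mean_b / mean_a:.1f}"
    return f"{name_a}:{name_b} = {mean_a / mean_b:.1f}:1"


def report(out_prefix, ratios=None, monte_carlo_result=None, cotter=None,
           histories=None, figures=False, maps=None):
    """Write a consolidated JSON + CSV summary (and optional map figures).

    Any subset of inputs may be given; empty input writes an empty report.
    ``ratios`` is a list of (name_a, name_b, mean_a, mean_b); ``maps`` is a
    list of (name, 2D array) rendered to PNG when ``figures`` is true.
    Returns the paths written; the JSON round-trips through
    :func:`load_report`.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    doc: dict = {}
    rows = []
    if ratios:
        doc["ratios"] = []
        for name_a, name_b, a, b in ratios:
            entry = {"pair": f"{name_a}:{name_b}", "mean_a": a, "mean_b": b,
                     "ratio": a / b, "display": format_ratio(name_a, name_b, a, b)}
            doc["ratios"].append(entry)
            rows.append({"metric": f"ratio {name_a}:{name_b}", "value": a / b,
                         "display": entry["display"]})
    if monte_carlo_result is not None:
        mc = monte_carlo_result
        doc["monte_carlo"] = {
            "n_replicates": mc.n_replicates, "n_failed": mc.n_failed,
            "bias": mc.bias, "precision": mc.precision,
            "bias_per_replicate": mc.bias_per_replicate,
        }
        rows += [{"metric": "bias", "value": mc.bias, "display": f"{mc.bias:.3f}"},
                 {"metric": "precision", "value": mc.precision,
                  "display": f"{mc.precision:.3f}"}]
    if cotter is not None:
        doc["cotter"] = cotter[["factor", "C_odd", "C_even", "M"]].to_dict("records")
        rows += [{"metric": f"cotter M({r.factor})", "value": r.M,
                  "display": f"{r.M:.4g}"} for r in cotter.itertuples()]
    if histories:
        doc["objective_histories"] = {k: list(map(float, v))
                                      for k, v in histories.items()}
    paths = []
    jpath = out_prefix.with_suffix(".json")
    jpath.write_text(json.dumps(doc, indent=2))
    paths.append(jpath)
    cpath = out_prefix.with_suffix(".csv")
    pd.DataFrame(rows, columns=["metric", "value", "display"]).to_csv(cpath, index=False)
    paths.append(cpath)
    if figures and maps:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for name, arr in maps:
            fig, ax = plt.subplots(figsize=(4, 4))
            im = ax.imshow(np.asarray(arr).T, origin="lower", cmap="viridis")
            fig.colorbar(im, ax=ax, label="relative stiffness")
            ax.set_title(name)
            p = out_prefix.parent / f"{out_prefix.name}_{name}.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            paths.append(p)
    return paths


def load_report(path) -> dict:
    """Read back a JSON report written by :func:`report`."""
    return json.loads(Path(path).read_text())
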