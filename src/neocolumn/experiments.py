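"""Scripted comparative experiments and the quadratic response-surface fit.

Each experiment runs the persistent-activity assay — build a column, drive
it with a binary image, score spike densities, the excited-neuron ratio
and the transfer accuracy — across repeats and conditions, and returns
tidy DataFrames (one row per repeat x pattern x condition).  Repeats
re-draw both the connectivity and the stimulus randomness by default; each
stream derives from the experiment seed so everything is reproducible.

The response-surface analysis regresses assay accuracy on five normalized
membrane parameters (C of L5/L6 PCs, V_th of the LL-INs of each layer),
each mapped so that the rodent value sits at 0 and the human value at 1,
with a quadratic-per-predictor model (no cross terms):

    accuracy = b0 + sum_i b_i x_i + sum_i g_i x_i^2
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .column import build_column
from .config import AEIF_FIELDS, AEIFBlock, ColumnConfig
from .engine import SimulationProtocol, run_simulation
from .metrics import excited_ratio, spike_density, summarize, transfer_accuracy
from .stimulus import (
    BinaryPattern,
    ImageStimulus,
    PATTERN_NAMES,
    add_salt_pepper,
    decode_output,
    encode_image,
    load_pattern,
)

__all__ = [
    "run_assay",
    "run_species_comparison",
    "morph_table",
    "morph_single_param",
    "sweep_background",
    "sweep_std_recovery",
    "noise_robustness",
    "RegressionFit",
    "fit_quadratic_response",
    "run_response_surface",
    "SURFACE_PREDICTORS",
]

Table = Dict[str, Dict[str, AEIFBlock]]

#: The five membrane parameters regressed against accuracy:
#: (predictor name, table layer, table class, field)
SURFACE_PREDICTORS: Tuple[Tuple[str, str, str, str], ...] = (
    ("C_L5PC", "L5", "PC", "C"),
    ("C_L6PC", "L6", "PC", "C"),
    ("Vth_L2/3LL-IN", "L2/3", "LL-IN", "V_th"),
    ("Vth_L5LL-IN", "L5", "LL-IN", "V_th"),
    ("Vth_L6LL-IN", "L6", "LL-IN", "V_th"),
)


def _repeat_seeds(seed: int, n: int) -> np.ndarray:
    """n (build, stimulus) seed pairs below 2^31 derived from one master seed."""
    state = np.random.SeedSequence(seed).generate_state(2 * n, dtype=np.uint32)
    return (state.reshape(n, 2) % np.uint32(2**31)).astype(np.int64)


def run_assay(
    config: ColumnConfig,
    species: str,
    pattern: BinaryPattern,
    n_repeats: Optional[int] = None,
    seed: int = 0,
    *,
    table: Optional[Table] = None,
    noise_proportion: float = 0.0,
    condition: str = "",
    freeze_connectivity: bool = False,
) -> pd.DataFrame:
    """The core assay: per repeat, build a column, stimulate with the image,
    and score the metrics of the run.

    Accuracy is always computed against the *clean* pattern; salt-and-pepper
    noise (``noise_proportion`` > 0) corrupts only the encoded input.
    Returns one row per repeat with the four metrics.
    """
    n_repeats = config.assay.n_repeats if n_repeats is None else n_repeats
    seeds = _repeat_seeds(seed, n_repeats)
    assay = config.assay
    stim_cfg = config.stimulus
    rows = []
    for rep in range(n_repeats):
        build_seed = int(seeds[0, 0]) if freeze_connectivity else int(seeds[rep, 0])
        stim_seed = int(seeds[rep, 1])
        network = build_column(config, species=species, seed=build_seed, table=table)
        stim_pattern = pattern
        if noise_proportion > 0:
            stim_pattern = add_salt_pepper(pattern, noise_proportion, seed=stim_seed)
        targets = encode_image(stim_pattern)
        stimulus = ImageStimulus(
            targets=targets,
            onset=stim_cfg.onset,
            stim_duration=stim_cfg.duration,
            mode=stim_cfg.mode,
            pulse_amplitude=stim_cfg.amplitude,
            poisson_rate=stim_cfg.poisson_rate,
            pulse_width=stim_cfg.pulse_width,
        )
        protocol = SimulationProtocol(
            duration=assay.t_end,
            dt=config.simulation.dt,
            stimulus=stimulus,
            seed=stim_seed,
        )
        raster, _ = run_simulation(network, protocol)
        rows.append(
            {
                "species": species if table is None else (condition or species),
                "condition": condition,
                "pattern": pattern.name,
                "repeat": rep,
                "build_seed": build_seed,
                "stim_seed": stim_seed,
                "noise_proportion": noise_proportion,
                "baseline_density": spike_density(raster, assay.baseline_window),
                "pa_density": spike_density(raster, assay.pa_window),
                "excited_ratio": (
                    excited_ratio(raster, targets, assay.baseline_window, assay.pa_window)
                    if targets
                    else float("nan")
                ),
                "accuracy": transfer_accuracy(
                    pattern, decode_output(raster, assay.decode_window)
                ),
            }
        )
    return pd.DataFrame(rows)


def _patterns(names: Optional[Sequence[str]] = None) -> List[BinaryPattern]:
    return [load_pattern(n) for n in (names or PATTERN_NAMES)]


def summarize_assay(df: pd.DataFrame, metric: str, group_col: str = "species"):
    """Mean +/- SEM per group and one-way ANOVA across groups of one metric."""
    groups = {g: sub[metric].to_numpy() for g, sub in df.groupby(group_col)}
    return summarize(groups)


def run_species_comparison(
    config: ColumnConfig,
    species: Sequence[str] = ("rodent", "human"),
    patterns: Optional[Sequence[str]] = None,
    n_repeats: Optional[int] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """The two-species assay: identical architecture, connectivity and
    stimulus seeds for every species; only the membrane-parameter table
    changes.  Returns the tidy per-repeat table."""
    frames = []
    for pat in _patterns(patterns):
        for sp in species:
            frames.append(
                run_assay(config, sp, pat, n_repeats=n_repeats, seed=seed, condition=sp)
            )
    return pd.concat(frames, ignore_index=True)


def morph_table(
    base: Table,
    source: Table,
    param: str,
    scope: Optional[Iterable[Tuple[str, str]]] = None,
    factor: Optional[float] = None,
) -> Table:
    """Clone ``base`` with one named membrane parameter replaced.

    ``param`` is one of C, g_L, E_L, V_r, V_th; ``scope`` limits the morph
    to given (layer, class) entries (default: every entry present in both
    tables).  When ``factor`` is given the morph instead scales the base
    value's distance from E_L by that factor (used for threshold probes
    such as "raise V_th a further 25%").
    """
    if param not in AEIF_FIELDS:
        raise ValueError(f"unknown parameter {param!r}; expected one of {AEIF_FIELDS}")
    out: Table = {
        layer: {cls: blk.model_copy() for cls, blk in classes.items()}
        for layer, classes in base.items()
    }
    for layer, classes in out.items():
        for cls_name, blk in classes.items():
            if scope is not None and (layer, cls_name) not in set(scope):
                continue
            if factor is not None:
                if param in ("V_th", "V_r"):
                    new_val = blk.E_L + factor * (getattr(blk, param) - blk.E_L)
                else:
                    new_val = factor * getattr(blk, param)
            else:
                if layer not in source or cls_name not in source[layer]:
                    continue
                new_val = getattr(source[layer][cls_name], param)
            classes[cls_name] = blk.model_copy(update={param: new_val})
    return out


def morph_single_param(
    config: ColumnConfig,
    base_species: str,
    param: str,
    source_species: Optional[str] = None,
    scope: Optional[Iterable[Tuple[str, str]]] = None,
    factor: Optional[float] = None,
    patterns: Optional[Sequence[str]] = None,
    n_repeats: Optional[int] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Assay with a single membrane parameter morphed between species.

    All other parameters stay at the ``base_species`` values, so any change
    in the report isolates the contribution of the named parameter.
    """
    base = config.aeif_tables[base_species]
    source = config.aeif_tables[source_species] if source_species else base
    table = morph_table(base, source, param, scope=scope, factor=factor)
    label = f"{base_species}+{param}" + (f"x{factor:g}" if factor else f"<-{source_species}")
    frames = [
        run_assay(
            config, base_species, pat, n_repeats=n_repeats, seed=seed,
            table=table, condition=label,
        )
        for pat in _patterns(patterns)
    ]
    return pd.concat(frames, ignore_index=True)


def sweep_background(
    config: ColumnConfig,
    levels: Sequence[Tuple[float, float]] = ((250.0, 200.0), (300.0, 250.0), (200.0, 150.0)),
    species: str = "rodent",
    patterns: Optional[Sequence[str]] = None,
    n_repeats: Optional[int] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Assay at several (excitatory, interneuron) background-current levels."""
    frames = []
    for pc_bg, in_bg in levels:
        cfg = config.model_copy(deep=True)
        cfg.background_currents.excitatory = pc_bg
        cfg.background_currents.inhibitory = in_bg
        label = f"bg({pc_bg:g},{in_bg:g})"
        for pat in _patterns(patterns):
            frames.append(
                run_assay(cfg, species, pat, n_repeats=n_repeats, seed=seed, condition=label)
            )
    return pd.concat(frames, ignore_index=True)


def sweep_std_recovery(
    config: ColumnConfig,
    tau_rec_values: Sequence[float] = (144.0, 200.0, 300.0, 400.0, 536.0),
    species: str = "human",
    patterns: Optional[Sequence[str]] = ("square",),
    n_repeats: Optional[int] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Assay with the depression-recovery time constant substituted globally.

    The default grid brackets the fast (144 ms) and slow (536 ms) recovery
    regimes around the 300 ms baseline; accuracy need not vary monotonically
    with tau_rec.
    """
    frames = []
    for tau in tau_rec_values:
        cfg = config.model_copy(deep=True)
        cfg.stp.tau_rec = float(tau)
        for pat in _patterns(patterns):
            frames.append(
                run_assay(
                    cfg, species, pat, n_repeats=n_repeats, seed=seed,
                    condition=f"tau_rec={tau:g}",
                )
            )
    return pd.concat(frames, ignore_index=True)


def noise_robustness(
    config: ColumnConfig,
    proportions: Sequence[float] = (0.0, 0.1, 0.2, 0.3),
    species: Sequence[str] = ("rodent", "human"),
    pattern: str = "square",
    n_repeats: Optional[int] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Salt-and-pepper robustness: corrupt the input image at several
    proportions and score accuracy against the clean pattern."""
    pat = load_pattern(pattern)
    frames = []
    for sp in species:
        for prop in proportions:
            frames.append(
                run_assay(
                    config, sp, pat, n_repeats=n_repeats, seed=seed,
                    noise_proportion=prop, condition=f"{sp}@noise{prop:g}",
                )
            )
    return pd.concat(frames, ignore_index=True)


@dataclass
class RegressionFit:
    """Quadratic-per-predictor response surface fit.

    ``linear[name]`` and ``quadratic[name]`` are the first- and
    second-order coefficients of each normalized predictor; ``intercept``
    the constant term.  ``vertex_form()`` rewrites each predictor's
    contribution as gamma * (x - x_vertex)^2 (plus a constant absorbed in
    the intercept), exposing the parabola axis per parameter.
    """

    predictors: Tuple[str, ...]
    intercept: float
    linear: Dict[str, float]
    quadratic: Dict[str, float]
    residuals: np.ndarray
    rss: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        y = np.full(X.shape[0], self.intercept)
        for j, name in enumerate(self.predictors):
            y += self.linear[name] * X[:, j] + self.quadratic[name] * X[:, j] ** 2
        return y

    def vertex_form(self) -> Dict[str, Tuple[float, float]]:
        """Per predictor: (x_vertex, curvature gamma) with the contribution
        gamma*(x - x_vertex)^2; predictors with |gamma| ~ 0 are skipped."""
        out = {}
        for name in self.predictors:
            g = self.quadratic[name]
            if abs(g) < 1e-12:
                continue
            out[name] = (-self.linear[name] / (2.0 * g), g)
        return out

    @property
    def vertex_intercept(self) -> float:
        """Constant term of the vertex form (intercept minus the completed
        squares' offsets)."""
        c = self.intercept
        for name in self.predictors:
            g = self.quadratic[name]
            if abs(g) >= 1e-12:
                c -= self.linear[name] ** 2 / (4.0 * g)
        return c


def fit_quadratic_response(
    X: np.ndarray,
    y: np.ndarray,
    predictors: Optional[Sequence[str]] = None,
    method: str = "ols",
) -> RegressionFit:
    """Fit accuracy = b0 + sum b_i x_i + sum g_i x_i^2 by least squares.

    ``X`` is (n_samples, n_predictors) of normalized parameters in [0, 1];
    ``y`` the accuracies (percent).  The model has no cross terms, so it is
    linear in the monomial basis and ``ols`` solves it directly.
    ``method='iterative'`` instead runs an iterative least-squares solver
    initialized at 1 for every coefficient; both converge to the same
    minimum for this linear-in-parameters model.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, d = X.shape
    names = tuple(predictors) if predictors else tuple(f"x{j}" for j in range(d))
    if len(names) != d:
        raise ValueError("predictor names must match X's column count")
    if n < 2 * d + 1:
        raise ValueError(f"need at least {2 * d + 1} samples for {d} predictors, got {n}")
    design = np.column_stack([np.ones(n), X, X**2])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            "rank-deficient design (a predictor may be constant across samples)"
        )
    if method == "ols":
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    elif method == "iterative":
        from scipy.optimize import least_squares

        res = least_squares(
            lambda c: design @ c - y, x0=np.ones(design.shape[1]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        coef = res.x
    else:
        raise ValueError(f"unknown method {method!r}")
    resid = y - design @ coef
    return RegressionFit(
        predictors=names,
        intercept=float(coef[0]),
        linear={nm: float(coef[1 + j]) for j, nm in enumerate(names)},
        quadratic={nm: float(coef[1 + d + j]) for j, nm in enumerate(names)},
        residuals=resid,
        rss=float(resid @ resid),
    )


def normalized_to_table(
    config: ColumnConfig,
    x: Sequence[float],
    base_species: str = "rodent",
    target_species: str = "human",
) -> Table:
    """Map a normalized predictor vector in [0,1]^5 to a parameter table:
    0 is the rodent value, 1 the human value, linear in between (the rodent
    -> human transition direction of each parameter)."""
    base = config.aeif_tables[base_species]
    target = config.aeif_tables[target_species]
    table: Table = {
        layer: {cls: blk.model_copy() for cls, blk in classes.items()}
        for layer, classes in base.items()
    }
    for xi, (name, layer, cls_name, fld) in zip(x, SURFACE_PREDICTORS):
        v0 = getattr(base[layer][cls_name], fld)
        v1 = getattr(target[layer][cls_name], fld)
        table[layer][cls_name] = table[layer][cls_name].model_copy(
            update={fld: v0 + float(xi) * (v1 - v0)}
        )
    return table


def run_response_surface(
    config: ColumnConfig,
    n_samples: int = 30,
    patterns: Optional[Sequence[str]] = ("square",),
    n_repeats: int = 3,
    seed: int = 0,
    base_species: str = "rodent",
    target_species: str = "human",
) -> tuple[pd.DataFrame, RegressionFit]:
    """Latin-hypercube sweep of the five predictors with a quadratic fit.

    Each sample interpolates the five surface parameters between the rodent
    (x=0) and human (x=1) values, runs the assay, and records the mean
    accuracy over patterns and repeats.
    """
    sampler = qmc.LatinHypercube(d=len(SURFACE_PREDICTORS), seed=seed)
    X = sampler.random(n_samples)
    names = [p[0] for p in SURFACE_PREDICTORS]
    rows = []
    for i, x in enumerate(X):
        table = normalized_to_table(config, x, base_species, target_species)
        accs = []
        for pat in _patterns(patterns):
            df = run_assay(
                config, base_species, pat, n_repeats=n_repeats,
                seed=seed + 1 + i, table=table, condition=f"surface{i}",
            )
            accs.append(df["accuracy"].mean())
        rows.append({**dict(zip(names, x)), "accuracy": float(np.mean(accs))})
    samples = pd.DataFrame(rows)
    fit = fit_quadratic_response(
        samples[names].to_numpy(), samples["accuracy"].to_numpy(), predictors=names
    )
    return samples, fit
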