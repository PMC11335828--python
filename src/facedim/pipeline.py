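"""End-to-end orchestration: per-population dimorphism analysis and the
synthetic validation study.

`analyze_population` reproduces the full analysis for one population:
symmetrize landmarks, joint Procrustes fit across both sexes, SShD by
projection onto the sex-mean axis with a permutation test on the
between-sex mean distance; overall skin color per channel with one-way
ANOVA; per-feature per-channel contrast ANOVA; SCoD on the skin-color +
contrast matrix with the same permutation test; attractiveness
correlations and inter-rater ICC(3,k).  Every excluded specimen is
enumerated with its reason, and every stochastic result records its seed,
so identical re-runs produce byte-identical reports.

`run_validation_suite` checks the pipeline against its own known-truth
generators: formula exactness, Procrustes invariance, projection algebra,
permutation type-I error, parameter recovery, and ICC calibration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import color as color_mod
from . import dimorphism as dim_mod
from . import stats as stats_mod
from .color import CHANNELS, ColorMeasurement, contrast_profile, mean_skin_color
from .dimorphism import (
    FeatureMatrix,
    assemble_scod_matrix,
    assemble_sshd_matrix,
    build_axis,
    mean_distance,
    project_scores,
)
from .landmarks import (
    LandmarkConfiguration,
    Pairing,
    gpa,
    read_pairing_csv,
    read_tps,
    symmetrize,
)
from .stats import anova_oneway, icc_3k, pearson_r, permutation_distance_test
from .synthetic import (
    PopulationSpec,
    RatingSpec,
    generate_colors,
    generate_landmarks,
    generate_ratings,
)

__all__ = [
    "RunConfig",
    "ReconciliationError",
    "simulate_population",
    "analyze_population",
    "run_population_analysis",
    "run_validation_suite",
]

logger = logging.getLogger(__name__)


class ReconciliationError(ValueError):
    """Raised when specimen ids cannot be reconciled across inputs."""


@dataclass
class RunConfig:
    """Configuration of a file-driven population analysis."""

    tps_path: str | None = None
    labels_path: str | None = None
    colors_path: str | None = None
    pairing_path: str | None = None
    ratings_paths: dict[str, str] = field(default_factory=dict)
    scod_channels: tuple[str, ...] = CHANNELS
    normalize_axis: bool = False
    standardize: bool = False
    n_perm: int = 10000
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_perm < 99:
            raise ValueError("n_perm must be >= 99")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a run configuration from a single YAML document."""
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        if "scod_channels" in data:
            data["scod_channels"] = tuple(data["scod_channels"])
        return cls(**data)


# ---------------------------------------------------------------------------
# Simulation bundle
# ---------------------------------------------------------------------------

def simulate_population(spec: PopulationSpec) -> dict:
    """Generate one synthetic population bundle: landmark configurations,
    color measurements, and one complete rating matrix per stimulus sex
    (female faces rated by males and vice versa), with the stimulus effect
    optionally coupled to each face's overall skin lightness."""
    configs = generate_landmarks(spec)
    measurements = generate_colors(spec)
    by_id = {m.specimen_id: m for m in measurements}
    ratings: dict[str, pd.DataFrame] = {}
    for sex, set_name in (("F", "female_faces"), ("M", "male_faces")):
        stimuli = [m.specimen_id for m in measurements if m.sex == sex]
        if len(stimuli) >= 2:
            lum = [mean_skin_color(by_id[s])[0] for s in stimuli]
            ratings[set_name] = generate_ratings(spec, stimuli, lum)
    return {
        "spec": spec,
        "landmarks": configs,
        "colors": measurements,
        "ratings": ratings,
    }


# ---------------------------------------------------------------------------
# Population analysis
# ---------------------------------------------------------------------------

def _anova_dict(values, labels) -> dict:
    try:
        return anova_oneway(values, labels).to_json_dict()
    except ValueError as exc:
        return {"error": str(exc)}


def analyze_population(
    configs: Sequence[LandmarkConfiguration],
    measurements: Sequence[ColorMeasurement],
    ratings: Mapping[str, pd.DataFrame] | None = None,
    scod_channels: Sequence[str] = CHANNELS,
    normalize_axis: bool = False,
    standardize: bool = False,
    n_perm: int = 10000,
    seed: int = 0,
) -> dict:
    """Full per-population analysis; returns a JSON-serializable report.

    Shape and color matrices apply listwise deletion independently;
    specimen ids must agree between the landmark and color inputs (orphans
    raise :class:`ReconciliationError`).
    """
    shape_ids = {c.specimen_id for c in configs}
    color_ids = {m.specimen_id for m in measurements}
    orphans = sorted(shape_ids.symmetric_difference(color_ids))
    if orphans:
        raise ReconciliationError(
            f"specimen ids differ between landmark and color inputs: {orphans}"
        )

    report: dict = {
        "seed": seed,
        "n_perm": n_perm,
        "n_specimens": len(configs),
        "populations": sorted({c.population for c in configs if c.population}),
    }

    # --- shape: symmetrize -> joint GPA -> SShD -------------------------------
    symmetrized = [symmetrize(c) for c in configs]
    aligned = gpa(symmetrized)
    shape_X = assemble_sshd_matrix(aligned)
    shape_perm = permutation_distance_test(shape_X, n_perm=n_perm, seed=seed)
    shape_axis = build_axis(shape_X)
    sshd_scores = project_scores(shape_X, shape_axis, normalize_axis=normalize_axis)
    report["shape"] = {
        "n_used": len(shape_X.specimen_ids),
        "excluded": [list(e) for e in shape_X.excluded],
        "gpa_iterations": aligned.iterations_run,
        "gpa_converged": aligned.converged,
        "mean_distance": shape_perm.observed_distance,
        "permutation": shape_perm.to_json_dict(),
    }

    # --- color: overall skin ANOVA per channel --------------------------------
    skin_rows = []
    skin_excluded = []
    for m in measurements:
        try:
            L, a, b = mean_skin_color(m)
        except color_mod.MissingRegionError as exc:
            skin_excluded.append([m.specimen_id, str(exc)])
            continue
        if m.sex in ("F", "M"):
            skin_rows.append((m.specimen_id, m.sex, L, a, b))
        else:
            skin_excluded.append([m.specimen_id, "sex label absent"])
    skin_df = pd.DataFrame(
        skin_rows, columns=["specimen_id", "sex", "L", "a", "b"]
    )
    report["skin_anova"] = {
        ch: _anova_dict(skin_df[ch].to_numpy(), skin_df["sex"].to_numpy())
        for ch in CHANNELS
    }
    report["skin_excluded"] = skin_excluded

    # --- contrasts: per-feature per-channel ANOVA -----------------------------
    profiles = [contrast_profile(m) for m in measurements]
    sex_by_id = {m.specimen_id: m.sex for m in measurements}
    contrast_report: dict = {}
    for feature in color_mod.FEATURE_REGIONS:
        contrast_report[feature] = {}
        for ch in CHANNELS:
            vals, labs = [], []
            n_missing = 0
            for p in profiles:
                v = p.get(feature, ch)
                sx = sex_by_id[p.specimen_id]
                if np.isnan(v) or sx not in ("F", "M"):
                    n_missing += 1
                    continue
                vals.append(v)
                labs.append(sx)
            entry = _anova_dict(vals, labs)
            entry["n_used"] = len(vals)
            entry["n_excluded"] = n_missing
            contrast_report[feature][ch] = entry
    report["contrast_anova"] = contrast_report

    # --- SCoD -----------------------------------------------------------------
    color_X = assemble_scod_matrix(
        measurements, profiles, channels=scod_channels, standardize=standardize
    )
    color_perm = permutation_distance_test(color_X, n_perm=n_perm, seed=seed + 1)
    color_axis = build_axis(color_X)
    scod_scores = project_scores(color_X, color_axis, normalize_axis=normalize_axis)
    report["color"] = {
        "n_used": len(color_X.specimen_ids),
        "excluded": [list(e) for e in color_X.excluded],
        "variables": color_X.variables,
        "mean_distance": color_perm.observed_distance,
        "permutation": color_perm.to_json_dict(),
    }

    # --- ratings: ICC and attractiveness-lightness correlation ----------------
    if ratings:
        lum_by_id = {
            row.specimen_id: row.L for row in skin_df.itertuples(index=False)
        }
        rating_report: dict = {}
        for set_name in sorted(ratings):
            R = ratings[set_name]
            icc = icc_3k(R)
            mean_rating = R.mean(axis=1)
            common = [s for s in R.index if s in lum_by_id]
            entry: dict = {"icc_3k": icc.icc_3k, "k": icc.k, "n": icc.n}
            if len(common) >= 3:
                r, pv = pearson_r(
                    [lum_by_id[s] for s in common],
                    mean_rating.loc[common].to_numpy(),
                )
                entry["attractiveness_vs_L"] = {"r": r, "p": pv, "n": len(common)}
            rating_report[set_name] = entry
        report["ratings"] = rating_report

    report["scores"] = {
        "sshd": sshd_scores.to_dict(orient="list"),
        "scod": scod_scores.to_dict(orient="list"),
    }
    report["axes"] = {
        "shape": shape_axis.to_json_dict(),
        "color": color_axis.to_json_dict(),
    }
    return report


def _violin_figure(report: dict, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(8, 4), sharey=False)
    for ax, space, title in zip(axes, ("sshd", "scod"), ("SShD", "SCoD")):
        tab = pd.DataFrame(report["scores"][space])
        groups = [
            tab.loc[tab.sex == s, "score"].to_numpy() for s in ("F", "M")
        ]
        parts = ax.violinplot(groups, showmedians=True)
        ax.set_xticks([1, 2], ["F", "M"])
        ax.set_title(title)
        ax.set_ylabel("projection score")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_population_analysis(config: RunConfig) -> dict:
    """File-driven analysis: read TPS landmarks, labels, color table and
    rating matrices per :class:`RunConfig`, analyze, and (when ``out_dir``
    is set) write the JSON report, score/axis CSVs and a violin figure."""
    if not (config.tps_path and config.colors_path):
        raise ValueError("tps_path and colors_path are required")
    configs = read_tps(config.tps_path)
    pairing: Pairing | None = None
    if config.pairing_path:
        pairing = read_pairing_csv(config.pairing_path)
    if config.labels_path:
        labels = pd.read_csv(config.labels_path).set_index("specimen_id")
        for c in configs:
            if c.specimen_id in labels.index:
                c.sex = str(labels.loc[c.specimen_id, "sex"])
                if "population" in labels.columns:
                    c.population = str(labels.loc[c.specimen_id, "population"])
    for c in configs:
        if pairing is not None:
            c.pairing = pairing
        c.validate_standard()
    measurements = color_mod.read_measurements_csv(config.colors_path)
    ratings = {
        name: pd.read_csv(path, index_col=0)
        for name, path in config.ratings_paths.items()
    }
    report = analyze_population(
        configs,
        measurements,
        ratings=ratings or None,
        scod_channels=config.scod_channels,
        normalize_axis=config.normalize_axis,
        standardize=config.standardize,
        n_perm=config.n_perm,
        seed=config.seed,
    )
    report["config"] = {
        "scod_channels": list(config.scod_channels),
        "normalize_axis": config.normalize_axis,
        "standardize": config.standardize,
        "n_perm": config.n_perm,
        "seed": config.seed,
    }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
        for space in ("sshd", "scod"):
            pd.DataFrame(report["scores"][space]).to_csv(
                out / f"{space}_scores.csv", index=False
            )
        (out / "axes.json").write_text(
            json.dumps(report["axes"], indent=2, sort_keys=True) + "\n"
        )
        _violin_figure(report, out / "dimorphism_scores.png")
    return report


# ---------------------------------------------------------------------------
# Validation suite
# ---------------------------------------------------------------------------

def _check(name: str, value: float, tolerance: float, passed: bool, **extra) -> dict:
    return {
        "check": name,
        "value": float(value),
        "tolerance": float(tolerance),
        "passed": bool(passed),
        **extra,
    }


def run_validation_suite(
    seed: int = 0,
    n_perm: int = 199,
    n_null_datasets: int = 200,
    n_recovery_per_sex: int = 200,
    shape_n_per_sex: int = 300,
) -> dict:
    """Self-validation against known-truth synthetic data.

    Returns a report with one pass/fail entry per check.  Defaults use
    reduced replication suitable for routine runs; the permutation type-I
    band widens automatically with fewer datasets.
    """
    rng = np.random.default_rng(seed)
    checks: list[dict] = []

    # 1. Michelson contrast vs direct arithmetic on an operand grid
    grid = [(f, s) for f in (1.0, 10.0, 35.5, 60.0, 99.0) for s in (2.0, 20.0, 50.0, 80.0)]
    err = max(
        abs(color_mod.michelson_contrast(f, s) - (s - f) / (f + s)) for f, s in grid
    )
    checks.append(_check("michelson_formula_exact", err, 1e-12, err <= 1e-12))

    # 2. projection algebra: mean sex score difference equals ||MM-FM||^2
    n, p = 40, 7
    X = FeatureMatrix(
        specimen_ids=[f"s{i}" for i in range(n)],
        sex_labels=["F"] * (n // 2) + ["M"] * (n // 2),
        variables=[f"v{j}" for j in range(p)],
        values=rng.normal(size=(n, p)) + np.r_[[0.0] * (n // 2), [1.0] * (n // 2)][:, None],
    )
    axis = build_axis(X)
    scores = project_scores(X, axis)
    diff = (
        scores.loc[scores.sex == "M", "score"].mean()
        - scores.loc[scores.sex == "F", "score"].mean()
    )
    err = abs(diff - axis.length**2)
    checks.append(_check("projection_identity", err, 1e-9, err <= 1e-9))

    # 3. GPA similarity invariance on a small synthetic population
    spec = PopulationSpec(name="val", n_female=10, n_male=10, seed=seed)
    configs = generate_landmarks(spec)
    aligned1 = gpa(configs)
    transformed = []
    for c in configs:
        theta = rng.uniform(-np.pi, np.pi)
        s = rng.uniform(0.3, 3.0)
        t = rng.uniform(-10, 10, size=2)
        R = np.array(
            [[np.cos(theta), np.sin(theta)], [-np.sin(theta), np.cos(theta)]]
        )
        transformed.append(
            LandmarkConfiguration(
                specimen_id=c.specimen_id,
                points=s * (c.points @ R) + t,
                sex=c.sex,
                pairing=c.pairing,
            )
        )
    aligned2 = gpa(transformed)
    flat1 = aligned1.coords.reshape(len(configs), -1)
    flat2 = aligned2.coords.reshape(len(configs), -1)
    from scipy.spatial.distance import pdist

    err = float(np.abs(pdist(flat1) - pdist(flat2)).max())
    checks.append(_check("gpa_similarity_invariance", err, 1e-6, err <= 1e-6))

    # 4. permutation type-I error under exchangeable labels
    alpha = 0.05
    p_attain = np.floor(alpha * (n_perm + 1)) / (n_perm + 1)
    half = 1.96 * np.sqrt(p_attain * (1 - p_attain) / n_null_datasets)
    rejections = 0
    ss = np.random.SeedSequence([seed, 11])
    for child in ss.spawn(n_null_datasets):
        r = np.random.default_rng(child)
        Xn = FeatureMatrix(
            specimen_ids=[f"s{i}" for i in range(20)],
            sex_labels=["F"] * 10 + ["M"] * 10,
            variables=["v1", "v2", "v3"],
            values=r.normal(size=(20, 3)),
        )
        res = permutation_distance_test(
            Xn, n_perm=n_perm, seed=int(child.generate_state(1)[0] % 2**31)
        )
        rejections += res.p_value <= alpha
    rate = rejections / n_null_datasets
    checks.append(
        _check(
            "permutation_type1_error",
            rate,
            half,
            abs(rate - p_attain) <= half,
            expected=p_attain,
            n_datasets=n_null_datasets,
            n_perm=n_perm,
        )
    )

    # 5a. color effect-size recovery at Delta/sigma = 2
    cspec = PopulationSpec(
        name="val_color",
        n_female=n_recovery_per_sex,
        n_male=n_recovery_per_sex,
        color_dimorphism={r: (-4.0, 0.0, 0.0) for r in color_mod.SKIN_REGIONS},
        color_noise_sd=(2.0, 1.0, 1.0),
        region_noise_sd=(0.5, 0.3, 0.3),
        seed=seed + 1,
    )
    meas = generate_colors(cspec)
    lum = [mean_skin_color(m)[0] for m in meas]
    sexes = [m.sex for m in meas]
    d = stats_mod.cohens_d(lum, sexes)
    checks.append(
        _check("color_d_recovery", abs(d) - 2.0, 0.35, abs(abs(d) - 2.0) <= 0.35, d=d)
    )

    # 5b. shape displacement recovery: truth from a noiseless two-face fit
    sspec = PopulationSpec(
        name="val_shape",
        n_female=shape_n_per_sex,
        n_male=shape_n_per_sex,
        seed=seed + 2,
    )
    truth = _true_shape_distance(sspec)
    sconfigs = generate_landmarks(sspec)
    saligned = gpa(sconfigs)
    sX = assemble_sshd_matrix(saligned)
    est = mean_distance(sX)
    rel = abs(est - truth) / truth
    checks.append(
        _check(
            "shape_distance_recovery",
            rel,
            0.05,
            rel <= 0.05,
            truth=truth,
            estimate=est,
            n_per_sex=shape_n_per_sex,
        )
    )

    # 6. ICC calibration at expected 0.95
    rspec = PopulationSpec(
        name="val_icc",
        rating_spec=RatingSpec(
            k_raters=30, stimulus_sd=0.8, rater_sd=0.5, noise_sd=1.0
        ),
        seed=seed + 3,
    )
    R = generate_ratings(rspec, [f"stim_{i}" for i in range(100)])
    icc = icc_3k(R).icc_3k
    expected = 0.8**2 / (0.8**2 + 1.0**2 / 30)
    checks.append(
        _check("icc_recovery", icc - expected, 0.03, abs(icc - expected) <= 0.03, icc=icc)
    )

    return {
        "seed": seed,
        "checks": checks,
        "all_passed": all(c["passed"] for c in checks),
    }


def _true_shape_distance(spec: PopulationSpec) -> float:
    """Procrustes-space magnitude of the male displacement, from a
    noiseless two-configuration fit (self-consistency oracle)."""
    from .synthetic import default_shape_displacement, make_face_template

    template = make_face_template(spec.template_style)
    delta = default_shape_displacement(template).reshape(-1, 2)
    female = LandmarkConfiguration(
        specimen_id="oracle_F", points=template.points, pairing=template.pairing
    )
    male = LandmarkConfiguration(
        specimen_id="oracle_M",
        points=template.points + spec.m_shape * delta,
        pairing=template.pairing,
    )
    aligned = gpa([female, male])
    return float(
        np.linalg.norm(aligned.coords[1].reshape(-1) - aligned.coords[0].reshape(-1))
    )
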