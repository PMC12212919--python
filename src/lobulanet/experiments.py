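"""Config-driven experiment pipelines.

Each experiment reproduces one of the model's headline analyses end-to-end:
receptive-field self-organisation, response sparseness and decorrelation,
single-unit tuning, scanning-condition behaviour, generalisation to other
pattern pairs, lobula population-size ablation, and the fixed-inhibition
ablation.  Every random draw descends from the experiment seed, and the run
manifest (config + seed) suffices to reproduce all tables.

Two built-in profiles set the problem sizes: ``paper`` keeps the full-scale
settings (50 lobula units, 50,000 training scans, 20 bees, 100 exposures, 50
tests), ``fast`` is a reduced configuration for desk-scale runs (16 units,
5,000 scans, 5 bees, 20 tests, 20 ms presentations).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import metrics, mushroom_body, plasticity, stimuli
from .mushroom_body import ConditioningProtocol, run_protocol
from .optic_lobe import GainConfig, LifParams, VisualLobeWeights
from .plasticity import LearningConfig, train_visual_lobe

__all__ = [
    "PROFILES",
    "EXPERIMENTS",
    "ExperimentConfig",
    "ResultsBundle",
    "run_experiment",
    "compare_conditions",
    "make_training_scenes",
    "pattern_scans",
]

PROFILES = {
    "paper": dict(n_lobula=50, n_kc=2000, n_patches=50_000, n_bees=20,
                  n_tests=50, n_exposures=100, duration=100.0, n_scenes=100),
    "fast": dict(n_lobula=16, n_kc=500, n_patches=5_000, n_bees=5,
                 n_tests=20, n_exposures=25, duration=20.0, n_scenes=20),
}

EXPERIMENTS = (
    "rf_training",
    "sparseness",
    "tuning",
    "scanning_conditions",
    "generalisation",
    "population_size",
    "fixed_inhibition",
)


@dataclass
class ExperimentConfig:
    """One experiment run: which pipeline, at which scale, from which seed."""

    experiment: str
    profile: str = "fast"
    seed: int = 0
    outdir: str | Path = "results"
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}; "
                             f"expected one of {EXPERIMENTS}")
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")

    def resolved(self) -> dict:
        p = dict(PROFILES[self.profile])
        p.update(self.overrides)
        return p


@dataclass
class ResultsBundle:
    """Tables, figure paths and the manifest of one experiment run."""

    tables: dict
    figures: dict = field(default_factory=dict)
    weights: VisualLobeWeights | None = None
    manifest: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(outdir / f"{name}.csv", index=False)
        if self.weights is not None:
            self.weights.save(outdir / "visual_lobe_weights.npz")
        (outdir / "manifest.json").write_text(json.dumps(self.manifest, indent=2))
        return outdir


# ---------------------------------------------------------------------------
# shared building blocks
# ---------------------------------------------------------------------------

def make_training_scenes(n_scenes: int, seed: int, shuffled: bool = False) -> list:
    """The synthetic stand-in for the natural flower/scene training set."""
    base = np.random.SeedSequence(seed).generate_state(n_scenes)
    scenes = [stimuli.make_synthetic_scene(int(s) % 2 ** 31) for s in base]
    if shuffled:
        scenes = [stimuli.shuffle_image(s, seed=int(b) % 2 ** 31)
                  for s, b in zip(scenes, base)]
    return scenes


def pretrain_lobe(prof: dict, seed: int, shuffled: bool = False,
                  plastic_q: bool = True, lif: LifParams | None = None,
                  gains: GainConfig | None = None):
    scenes = make_training_scenes(prof["n_scenes"], seed, shuffled=shuffled)
    cfg = LearningConfig(n_patches=prof["n_patches"], seed=seed, plastic_q=plastic_q)
    return train_visual_lobe(scenes, cfg, lif=lif, gains=gains,
                             n_lobula=prof["n_lobula"])


def pattern_scans(kind_a: str = "plus", kind_b: str = "multiplication",
                  region: str = "lower_half", shift_px: int = 15,
                  distal: bool = False, params_a: dict | None = None,
                  params_b: dict | None = None):
    """Scan pair (S+, S-) for a discrimination task under one condition."""
    pat_a = stimuli.make_pattern(kind_a, params_a)
    pat_b = stimuli.make_pattern(kind_b, params_b)
    if distal:
        pat_a = stimuli.distal_view(pat_a)
        pat_b = stimuli.distal_view(pat_b)
    scan_a = stimuli.make_scan(pat_a, region=region, shift_px=shift_px)
    scan_b = stimuli.make_scan(pat_b, region=region, shift_px=shift_px)
    return scan_a, scan_b


def _held_out_scan_responses(lobe: VisualLobeWeights, scenes, n_scans: int,
                             seed: int, lif: LifParams, gains: GainConfig) -> np.ndarray:
    """Lobula population responses to random held-out scene scans."""
    from .optic_lobe import lobula_response

    rng = np.random.default_rng(seed)
    span = stimuli.PATCH_SIZE + (stimuli.M_PATCHES - 1) * 15
    out = np.zeros((n_scans, lobe.n_lobula))
    for i in range(n_scans):
        scene = scenes[rng.integers(len(scenes))]
        h, w = scene.pixels.shape
        row = int(rng.integers(0, h - stimuli.PATCH_SIZE + 1))
        col = int(rng.integers(0, w - span + 1))
        scan = stimuli.make_scan(scene, region="custom", shift_px=15,
                                 window_row=row, col_start=col)
        out[i] = lobula_response(scan, lobe, p=lif, gains=gains, rng=rng).rates
    return out


# ---------------------------------------------------------------------------
# pipelines
# ---------------------------------------------------------------------------

def _exp_rf_training(cfg: ExperimentConfig, prof, lif, gains) -> ResultsBundle:
    lobe, hist = pretrain_lobe(prof, cfg.seed, lif=lif, gains=gains)
    osi = metrics.population_osi(lobe, n_reps=3, seed=cfg.seed, lif=lif, gains=gains)
    tables = {
        "training_history": hist.to_frame(),
        "osi": pd.DataFrame({"unit": np.arange(lobe.n_lobula), "osi": osi}),
    }
    return ResultsBundle(tables=tables, weights=lobe)


def _exp_sparseness(cfg: ExperimentConfig, prof, lif, gains) -> ResultsBundle:
    from .optic_lobe import init_visual_lobe

    scenes = make_training_scenes(prof["n_scenes"], cfg.seed)
    held_out = make_training_scenes(prof["n_scenes"] // 2, cfg.seed + 1)
    naive = init_visual_lobe(prof["n_lobula"], seed=cfg.seed)
    trained, _ = pretrain_lobe(prof, cfg.seed, lif=lif, gains=gains)
    shuf, _ = pretrain_lobe(prof, cfg.seed, shuffled=True, lif=lif, gains=gains)

    n_scans = 50
    rows = []
    resp = {}
    for name, lobe in (("pre", naive), ("natural", trained), ("shuffled", shuf)):
        R = _held_out_scan_responses(lobe, held_out, n_scans, cfg.seed + 2, lif, gains)
        resp[name] = R
        si = [metrics.sparseness_index(r) for r in R if r.any()]
        _, mean_off, _ = metrics.response_correlation(R)
        rows.append({"condition": name, "sparseness_mean": float(np.mean(si)),
                     "sparseness_sem": float(np.std(si, ddof=1) / np.sqrt(len(si))),
                     "mean_abs_offdiag_corr": mean_off})
    del scenes
    return ResultsBundle(tables={"sparseness": pd.DataFrame(rows)})


def _exp_tuning(cfg: ExperimentConfig, prof, lif, gains) -> ResultsBundle:
    lobe, _ = pretrain_lobe(prof, cfg.seed, lif=lif, gains=gains)
    osi = metrics.population_osi(lobe, n_reps=3, seed=cfg.seed, lif=lif, gains=gains)
    unit = int(np.argmax(osi))
    ocurve, u_osi = metrics.orientation_tuning(lobe, unit, n_reps=10, seed=cfg.seed,
                                               lif=lif, gains=gains)
    vcurve, fit = metrics.velocity_tuning(lobe, unit, n_reps=10, seed=cfg.seed,
                                          angle=ocurve.preferred, lif=lif, gains=gains)
    tables = {
        "orientation_tuning": pd.DataFrame({"angle_deg": ocurve.abscissa,
                                            "rate": ocurve.rates, "sem": ocurve.sem}),
        "velocity_tuning": pd.DataFrame({"shift_px": vcurve.abscissa,
                                         "rate": vcurve.rates, "sem": vcurve.sem}),
        "summary": pd.DataFrame([{"unit": unit, "osi": u_osi,
                                  "preferred_angle": ocurve.preferred,
                                  "gamma_k": fit["k"], "gamma_theta": fit["theta"],
                                  "peak_velocity_px": fit["peak_velocity"]}]),
    }
    return ResultsBundle(tables=tables, weights=lobe)


#: behavioural scanning conditions; lower_left at the fast speed cannot fit
#: a traverse inside the quadrant and is reported as NaN
SCAN_CONDITIONS = [
    ("lower_half", 15), ("lower_half", 0), ("lower_half", 45),
    ("lower_left", 15), ("lower_left", 0), ("lower_left", 45),
    ("whole_fit", 15), ("whole_fit", 0), ("whole_fit", 45),
]


def _exp_scanning(cfg: ExperimentConfig, prof, lif, gains) -> ResultsBundle:
    lobe, _ = pretrain_lobe(prof, cfg.seed, lif=lif, gains=gains)
    rows = []
    for distal in (False, True):
        for region, shift in SCAN_CONDITIONS:
            proto = ConditioningProtocol(n_exposures=prof["n_exposures"],
                                         n_bees=prof["n_bees"], n_tests=prof["n_tests"],
                                         n_kc=prof["n_kc"], seed=cfg.seed)
            try:
                scan_p, scan_m = pattern_scans(region=region, shift_px=shift,
                                               distal=distal)
            except ValueError:
                rows.append({"region": region, "shift_px": shift, "distal": distal,
                             "accuracy_mean": np.nan, "accuracy_sem": np.nan})
                continue
            table, _ = run_protocol(proto, lobe, scan_p, scan_m, lif=lif, gains=gains)
            rows.append({
                "region": region, "shift_px": shift, "distal": distal,
                "accuracy_mean": table["accuracy"].mean(),
                "accuracy_sem": table["accuracy"].sem(),
            })
    return ResultsBundle(tables={"scanning_accuracy": pd.DataFrame(rows)}, weights=lobe)


GENERALISATION_TASKS = {
    "bars_90deg": dict(kind_a="bar", kind_b="bar",
                       params_a={"angle": 45.0}, params_b={"angle": 135.0}),
    "crosses_rotated": dict(kind_a="plus", kind_b="multiplication"),
    "mirrored_spirals": dict(kind_a="spiral", kind_b="spiral",
                             params_a={"handedness": 1.0}, params_b={"handedness": -1.0}),
}


def _exp_generalisation(cfg: ExperimentConfig, prof, lif, gains) -> ResultsBundle:
    lobe, _ = pretrain_lobe(prof, cfg.seed, lif=lif, gains=gains)
    rows = []
    for task, kw in GENERALISATION_TASKS.items():
        proto = ConditioningProtocol(n_exposures=prof["n_exposures"] // 2,
                                     n_bees=prof["n_bees"], n_tests=prof["n_tests"],
                                     n_kc=prof["n_kc"], seed=cfg.seed)
        scan_p, scan_m = pattern_scans(region="lower_half", shift_px=15, **kw)
        table, _ = run_protocol(proto, lobe, scan_p, scan_m, lif=lif, gains=gains)
        rows.append({"task": task, "accuracy_mean": table["accuracy"].mean(),
                     "accuracy_sem": table["accuracy"].sem()})
    return ResultsBundle(tables={"generalisation": pd.DataFrame(rows)}, weights=lobe)


def _exp_population_size(cfg: ExperimentConfig, prof, lif, gains) -> ResultsBundle:
    rows = []
    for n_lobula in (4, 16, 36, prof["n_lobula"]):
        p = dict(prof, n_lobula=n_lobula)
        lobe, _ = pretrain_lobe(p, cfg.seed, lif=lif, gains=gains)
        proto = ConditioningProtocol(n_exposures=prof["n_exposures"],
                                     n_bees=prof["n_bees"], n_tests=prof["n_tests"],
                                     n_kc=prof["n_kc"], seed=cfg.seed)
        scan_p, scan_m = pattern_scans(region="lower_half", shift_px=15)
        table, _ = run_protocol(proto, lobe, scan_p, scan_m, lif=lif, gains=gains)
        rows.append({"n_lobula": n_lobula, "accuracy_mean": table["accuracy"].mean(),
                     "accuracy_sem": table["accuracy"].sem()})
    return ResultsBundle(tables={"population_size": pd.DataFrame(rows)})


def _exp_fixed_inhibition(cfg: ExperimentConfig, prof, lif, gains) -> ResultsBundle:
    rows = []
    for plastic in (True, False):
        lobe, _ = pretrain_lobe(prof, cfg.seed, plastic_q=plastic, lif=lif, gains=gains)
        osi = metrics.population_osi(lobe, n_reps=3, seed=cfg.seed, lif=lif, gains=gains)
        proto = ConditioningProtocol(n_exposures=prof["n_exposures"],
                                     n_bees=prof["n_bees"], n_tests=prof["n_tests"],
                                     n_kc=prof["n_kc"], seed=cfg.seed)
        scan_p, scan_m = pattern_scans(region="lower_half", shift_px=15)
        table, _ = run_protocol(proto, lobe, scan_p, scan_m, lif=lif, gains=gains)
        rows.append({"plastic_q": plastic,
                     "n_selective": int((osi > 0.3).sum()),
                     "n_units": lobe.n_lobula,
                     "accuracy_mean": table["accuracy"].mean(),
                     "accuracy_sem": table["accuracy"].sem()})
    return ResultsBundle(tables={"fixed_inhibition": pd.DataFrame(rows)})


_PIPELINES = {
    "rf_training": _exp_rf_training,
    "sparseness": _exp_sparseness,
    "tuning": _exp_tuning,
    "scanning_conditions": _exp_scanning,
    "generalisation": _exp_generalisation,
    "population_size": _exp_population_size,
    "fixed_inhibition": _exp_fixed_inhibition,
}


def run_experiment(cfg: ExperimentConfig, write: bool = True) -> ResultsBundle:
    """Execute one named experiment pipeline and (optionally) write its bundle."""
    prof = cfg.resolved()
    lif = LifParams(duration=prof["duration"])
    gains = GainConfig()
    bundle = _PIPELINES[cfg.experiment](cfg, prof, lif, gains)
    bundle.manifest = {"config": {**asdict(cfg), "outdir": str(cfg.outdir)},
                       "profile_resolved": prof,
                       "numpy_version": np.__version__}
    if write:
        bundle.write(Path(cfg.outdir) / cfg.experiment)
    return bundle


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def compare_conditions(groups: dict[str, np.ndarray], pairing: str = "independent",
                       alpha: float = 0.05) -> pd.DataFrame:
    """Nonparametric comparison of accuracy groups.

    Two groups: Wilcoxon signed-rank (``pairing='matched'``) or rank-sum /
    Mann-Whitney U (``'independent'``).  More than two groups: Kruskal-Wallis
    followed by Dunn's post hoc test (pairwise z on mean ranks, Bonferroni
    corrected).  Returns one row per comparison with statistic, p and a
    significance flag at ``alpha``.  All-zero matched differences are
    reported with p = NaN and flagged undefined.
    """
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    rows = []
    if len(arrays) == 2:
        a, b = arrays
        if pairing == "matched":
            if len(a) != len(b):
                raise ValueError("matched groups must have equal size")
            d = a - b
            if np.all(d == 0):
                rows.append({"comparison": f"{names[0]} vs {names[1]}",
                             "test": "wilcoxon_signed_rank", "statistic": np.nan,
                             "p": np.nan, "significant": False, "undefined": True})
            else:
                st, p = stats.wilcoxon(a, b)
                rows.append({"comparison": f"{names[0]} vs {names[1]}",
                             "test": "wilcoxon_signed_rank", "statistic": float(st),
                             "p": float(p), "significant": p < alpha, "undefined": False})
        else:
            st, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            rows.append({"comparison": f"{names[0]} vs {names[1]}",
                         "test": "mann_whitney_u", "statistic": float(st),
                         "p": float(p), "significant": p < alpha, "undefined": False})
        return pd.DataFrame(rows)

    st, p = stats.kruskal(*arrays)
    rows.append({"comparison": "omnibus", "test": "kruskal_wallis",
                 "statistic": float(st), "p": float(p),
                 "significant": p < alpha, "undefined": False})
    # Dunn's post hoc: pairwise z on mean ranks, Bonferroni corrected
    all_vals = np.concatenate(arrays)
    ranks = stats.rankdata(all_vals)
    splits = np.cumsum([len(a) for a in arrays])[:-1]
    group_ranks = np.split(ranks, splits)
    n_total = len(all_vals)
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_corr = np.sum(tie_counts ** 3 - tie_counts) / (12.0 * (n_total - 1))
    n_pairs = len(arrays) * (len(arrays) - 1) // 2
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            ri, rj = group_ranks[i].mean(), group_ranks[j].mean()
            se = np.sqrt((n_total * (n_total + 1) / 12.0 - tie_corr)
                         * (1.0 / len(arrays[i]) + 1.0 / len(arrays[j])))
            z = (ri - rj) / se if se > 0 else np.nan
            p_ij = min(1.0, 2.0 * stats.norm.sf(abs(z)) * n_pairs)
            rows.append({"comparison": f"{names[i]} vs {names[j]}",
                         "test": "dunn_posthoc", "statistic": float(z),
                         "p": float(p_ij), "significant": p_ij < alpha,
                         "undefined": False})
    return pd.DataFrame(rows)
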