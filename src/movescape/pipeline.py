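"""End-to-end orchestration and study-level summaries.

Runs clean -> subsample/bursts -> home ranges + landscape classes -> HMM
fits (2-4 states per landscape class, assessed by plausibility, predictive
power and AIC) -> decoding -> behavioral metrics, and assembles report
tables: per-landscape home-range size/complexity summaries and per-state
movement summaries (time budgets, foraging:traveling ratio). Group
differences are compared with a seeded two-sided permutation test on the
difference of means (the test is named in the report output).

The packaged demo configuration simulates a three-landscape study whose
movement regimes and time budgets are the study conditions the package is
validated against.
"""
from __future__ import annotations

import dataclasses
import itertools
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import homerange as hr
from . import preprocess as pp
from . import simulate as sim
from .hmm import MovementHMM, MovementHMMResults, build_start_grid
from .tracks import Track, read_tracks

MIN_MONITORING_DAYS = 90.0


@dataclasses.dataclass
class TimeBudget:
    """Per-state proportions of decoded steps (pooled over bursts)."""

    proportions: np.ndarray          # indexed by 0-based state
    n_steps: int
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if abs(self.proportions.sum() - 1.0) > 1e-12:
            raise ValueError("proportions must sum to 1")
        if np.any((self.proportions < 0) | (self.proportions > 1)):
            raise ValueError("proportions must lie in [0, 1]")

    def by_label(self) -> dict[str, float]:
        return dict(zip(self.labels, self.proportions))


def time_budget(state_sequences, n_states: int, labels=()) -> TimeBudget:
    """Pooled fraction of decoded steps in each state (states are 1-based)."""
    pooled = np.concatenate([np.asarray(s) for s in state_sequences])
    if pooled.size == 0:
        raise ValueError("no decoded steps")
    counts = np.bincount(pooled - 1, minlength=n_states)
    return TimeBudget(counts / counts.sum(), int(pooled.size), tuple(labels))


def foraging_travel_ratio(budget: TimeBudget) -> float:
    """Time spent foraging over time spent traveling (unrounded proportions)."""
    props = budget.by_label()
    if "foraging" not in props or "traveling" not in props:
        raise ValueError("budget must carry 3-state labels incl. foraging/traveling")
    if props["traveling"] == 0:
        raise ValueError("traveling proportion is zero; ratio undefined")
    return props["foraging"] / props["traveling"]


def compare_groups(
    groups: dict[str, np.ndarray],
    n_permutations: int = 9999,
    seed: int = 0,
    exact: bool | str = "auto",
) -> dict[tuple[str, str], dict]:
    """Two-sided permutation tests on the difference of group means.

    For each pair of groups the statistic is ``mean(a) - mean(b)``;
    p = (1 + #{|T_perm| >= |T_obs|}) / (1 + n_draws). With ``exact`` (or
    'auto' and a small pooled sample) all label assignments are enumerated
    instead of sampled, and p is the exact tail fraction.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for (na, a), (nb, b) in itertools.combinations(groups.items(), 2):
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError("need at least 2 values per group")
        pooled = np.concatenate([a, b])
        t_obs = a.mean() - b.mean()
        n, n1 = pooled.size, a.size
        use_exact = exact is True or (exact == "auto" and math.comb(n, n1) <= 20000)
        if use_exact:
            total = pooled.sum()
            count = 0
            n_comb = 0
            for idx in itertools.combinations(range(n), n1):
                sa = pooled[list(idx)].sum()
                t = sa / n1 - (total - sa) / (n - n1)
                count += abs(t) >= abs(t_obs) - 1e-12
                n_comb += 1
            p = count / n_comb
        else:
            count = 0
            for _ in range(n_permutations):
                perm = rng.permutation(pooled)
                t = perm[:n1].mean() - perm[n1:].mean()
                count += abs(t) >= abs(t_obs) - 1e-12
            p = (1 + count) / (1 + n_permutations)
        out[(na, nb)] = {
            "statistic": float(t_obs),
            "p_value": float(p),
            "exact": bool(use_exact),
            "test": "two-sided permutation test on difference of means",
        }
    return out


def _se(values: np.ndarray) -> float:
    """Sample SD / sqrt(n); undefined (NaN) for fewer than 2 values."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        return float("nan")
    return float(values.std(ddof=1) / np.sqrt(values.size))


def summarize_landscape(animals: list[dict], class_results: dict[str, dict]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate per-landscape space-use and movement tables.

    ``animals`` carry per-animal home-range results (after deduplication);
    ``class_results`` carry the accepted model, decoded states and step
    data per landscape class. Returns (space-use table, movement table).
    """
    space_rows = []
    for cls in sorted({a["landscape"] for a in animals}):
        members = [a for a in animals if a["landscape"] == cls]
        hr95 = np.array([a["locoh_hr_km2"] for a in members])
        hr50 = np.array([a["locoh_core_km2"] for a in members])
        c95 = np.array([a["complexity_hr"] for a in members])
        c50 = np.array([a["complexity_core"] for a in members])
        comps = np.array([a["n_components_hr"] for a in members])
        space_rows.append(
            {
                "landscape": cls,
                "n_home_ranges": len(members),
                "home_range_km2_mean": hr95.mean(),
                "home_range_km2_se": _se(hr95),
                "core_km2_mean": hr50.mean(),
                "core_km2_se": _se(hr50),
                "complexity_hr_mean": c95.mean(),
                "complexity_hr_se": _se(c95),
                "complexity_core_mean": c50.mean(),
                "complexity_core_se": _se(c50),
                "components_mean": comps.mean(),
                "components_min": int(comps.min()),
                "components_max": int(comps.max()),
            }
        )
    move_rows = []
    for cls, res in sorted(class_results.items()):
        if res.get("best_k") is None:
            continue
        budget: TimeBudget = res["budget"]
        lengths = res["step_lengths"]
        states = res["decoded_states"]
        labels = res["labels"]
        for k, label in enumerate(labels):
            in_state = lengths[states == k + 1]
            move_rows.append(
                {
                    "landscape": cls,
                    "n_states": len(labels),
                    "state": label,
                    "n_steps": int(in_state.size),
                    "step_mean_m": in_state.mean() if in_state.size else np.nan,
                    "step_sd_m": in_state.std(ddof=1) if in_state.size > 1 else np.nan,
                    "step_min_m": in_state.min() if in_state.size else np.nan,
                    "step_max_m": in_state.max() if in_state.size else np.nan,
                    "time_spent": budget.proportions[k],
                    "foraging_travel_ratio": res.get("ratio"),
                }
            )
    return pd.DataFrame(space_rows), pd.DataFrame(move_rows)


# ---------------------------------------------------------------------------
# demo study configuration

#: Movement regimes used by the packaged demo study: per-landscape state
#: means/SDs (m), stationary time budgets, and angle parameters. Encamped
#: and foraging states turn sharply (mean pi, low concentration); traveling
#: is directed (mean 0, higher concentration).
DEMO_REGIMES = {
    "natural_fragment": {
        "step_means": [7.4, 306.0],
        "step_sds": [8.3, 238.0],
        "budget": [0.57, 0.43],
        "angle_means": [np.pi, 0.0],
        "kappas": [0.5, 1.5],
    },
    "suburban": {
        "step_means": [7.6, 130.0, 528.0],
        "step_sds": [7.2, 114.0, 218.0],
        "budget": [0.58, 0.25, 0.19],
        "angle_means": [np.pi, np.pi, 0.0],
        "kappas": [0.5, 0.7, 2.0],
    },
    "highly_urbanized": {
        "step_means": [7.5, 122.0, 625.0],
        "step_sds": [7.2, 114.0, 385.0],
        "budget": [0.62, 0.21, 0.20],
        "angle_means": [np.pi, np.pi, 0.0],
        "kappas": [0.5, 0.7, 2.0],
    },
}

# anchor x-positions (m) on the demo west-east imperviousness ramp chosen so
# home ranges average ~10 / ~35 / ~60 percent imperviousness
_DEMO_ANCHORS_X = {"natural_fragment": 6000.0, "suburban": 21000.0, "highly_urbanized": 36000.0}


def demo_config(
    seed: int = 0,
    n_animals_per_class: int = 2,
    n_days: float = 100.0,
    n_burst_windows: int = 3,
    burst_window_h: float = 36.0,
    zero_mass: float = 0.02,
    n_spikes: int = 2,
) -> dict:
    """Configuration for a fully simulated three-landscape study."""
    return {
        "seed": int(seed),
        "tracks": {
            "simulate": {
                "n_animals_per_class": int(n_animals_per_class),
                "n_days": float(n_days),
                "n_burst_windows": int(n_burst_windows),
                "burst_window_h": float(burst_window_h),
                "zero_mass": float(zero_mass),
                "n_spikes": int(n_spikes),
                "attraction": 0.3,
                "anchor_switch_steps": 192,
            }
        },
        "raster": {
            "simulate": {
                "extent": [0.0, 0.0, 42000.0, 14000.0],
                "cell_size": 60.0,
                "pattern": "gradient",
                "level": 70.0,
            }
        },
        "clean": {"hard_kmh": pp.HARD_SPEED_KMH, "review_kmh": pp.REVIEW_SPEED_KMH},
        "homerange": {
            "levels": [0.5, 0.95],
            "min_days": MIN_MONITORING_DAYS,
            "allow_short": False,
        },
        "hmm": {
            "n_states": [2, 3, 4],
            "separation_threshold": 2.0,
            "start_grid": {"kappa_candidates": [0.5]},
        },
        "report": {"n_permutations": 999},
    }


def _simulate_study(spec: dict, seed: int) -> list[Track]:
    """Simulate the demo tracks: anchored movement on mixed fix schedules."""
    rng = np.random.default_rng(seed)
    tracks = []
    n_steps = int(spec["n_days"] * 96)  # 15-min base schedule
    for cls, regime in DEMO_REGIMES.items():
        K = len(regime["step_means"])
        tmat = sim.transition_matrix_for_stationary(
            np.asarray(regime["budget"]) / np.sum(regime["budget"]), 0.3
        )
        for j in range(spec["n_animals_per_class"]):
            child = int(rng.integers(2**31 - 1))
            base = np.array(
                [_DEMO_ANCHORS_X[cls] + rng.uniform(-1500, 1500),
                 7000.0 + rng.uniform(-2000, 2000)]
            )
            # den plus two satellite activity patches
            anchors = base + np.array([[0.0, 0.0], [2000.0, 600.0], [900.0, -1500.0]])
            config = sim.SimulationConfig(
                n_states=K,
                step_means=regime["step_means"],
                step_sds=regime["step_sds"],
                zero_mass=np.full(K, spec["zero_mass"]),
                angle_means=regime["angle_means"],
                kappas=regime["kappas"],
                tmat=tmat,
                fix_interval_s=900.0,
                n_steps=n_steps,
                start=tuple(base),
                seed=child,
                anchor=anchors,
                attraction=spec["attraction"],
                anchor_switch_steps=int(spec.get("anchor_switch_steps", 0)),
            )
            track = sim.simulate_territorial_track(config, animal_id=f"{cls[:3]}{j + 1}")
            # mixed collar schedule: 15-min fixes inside the burst windows,
            # one fix per 7.25 h elsewhere
            keep = np.zeros(len(track), dtype=bool)
            keep[::29] = True  # 29 x 15 min = 7.25 h
            window_len = int(spec["burst_window_h"] * 4)
            starts = np.linspace(
                0, len(track) - window_len - 2, spec["n_burst_windows"]
            ).astype(int)
            for s in starts:
                keep[s : s + window_len + 1] = True
            sampled = track.subset(np.flatnonzero(keep))
            if spec["n_spikes"] > 0:
                # spikes land inside the 15-min windows, where the speed rule
                # can catch them (15 km in 15 min = 60 km/h)
                gaps = np.diff(sampled.times)
                fast = np.flatnonzero((gaps[:-1] == 900.0) & (gaps[1:] == 900.0)) + 1
                sampled, _ = sim.inject_position_errors(
                    sampled, spec["n_spikes"], 15000.0, seed=child + 1,
                    candidate_indices=fast,
                )
            tracks.append(sampled)
    return tracks


@dataclasses.dataclass
class PipelineReport:
    """Bundle of everything an end-to-end run produces."""

    config: dict
    animals: list[dict]
    class_results: dict[str, dict]
    space_table: pd.DataFrame
    movement_table: pd.DataFrame
    comparisons: dict
    log: list[str]
    homerange_estimates: list = dataclasses.field(default_factory=list)

    def summary_dict(self) -> dict:
        def clean(v):
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            if isinstance(v, float) and math.isnan(v):
                return None
            return v

        return {
            "n_animals": len(self.animals),
            "landscape_classes": sorted({a["landscape"] for a in self.animals}),
            "space_use": [
                {k: clean(v) for k, v in row.items()}
                for row in self.space_table.to_dict("records")
            ],
            "movement": [
                {k: clean(v) for k, v in row.items()}
                for row in self.movement_table.to_dict("records")
            ],
            "model_selection": {
                cls: {
                    "aic": {str(k): r["fits"][k].aic for k in r["fits"]},
                    "accepted_n_states": r.get("best_k"),
                    "rejected": r.get("rejected", {}),
                }
                for cls, r in self.class_results.items()
            },
            "comparisons": {
                f"{a} vs {b}": v for (a, b), v in self.comparisons.items()
            },
            "log": self.log,
        }

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.space_table.to_csv(out / "space_use.csv", index=False)
        self.movement_table.to_csv(out / "movement.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(self.summary_dict(), fh, indent=2, sort_keys=True)
        if self.homerange_estimates:
            hr.to_geojson(self.homerange_estimates, out / "homeranges.geojson")
        (out / "run.log").write_text("\n".join(self.log) + "\n")


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def run_pipeline(config: dict | str | Path, out_dir=None) -> PipelineReport:
    """Execute the full analysis described by ``config``.

    Deterministic given the config (which carries the seed): the same
    configuration always yields byte-identical report files.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    seed = int(config.get("seed", 0))
    log: list[str] = [f"seed: {seed}"]

    # --- inputs -----------------------------------------------------------
    tracks_cfg = config["tracks"]
    if "simulate" in tracks_cfg:
        tracks = _simulate_study(tracks_cfg["simulate"], seed)
        log.append(f"simulated {len(tracks)} tracks")
    else:
        tracks = read_tracks(tracks_cfg["csv"])
        log.append(f"read {len(tracks)} tracks from {tracks_cfg['csv']}")
    strategies = tracks_cfg.get("strategies", {})

    raster_cfg = config["raster"]
    if "simulate" in raster_cfg:
        rc = dict(raster_cfg["simulate"])
        raster = sim.make_imperviousness_raster(
            tuple(rc.pop("extent")), seed=seed, **rc
        )
    else:
        raster = sim.ImperviousnessRaster.load(raster_cfg["load"])

    # --- cleaning ---------------------------------------------------------
    clean_cfg = config.get("clean", {})
    cleaned = []
    for track in tracks:
        flagged = pp.flag_speed_outliers(
            track, clean_cfg.get("review_kmh", pp.REVIEW_SPEED_KMH)
        )
        ct, removals = pp.remove_spikes(
            track, clean_cfg.get("hard_kmh", pp.HARD_SPEED_KMH)
        )
        log.append(
            f"{track.animal_id}: {len(flagged)} fixes flagged for review, "
            f"{len(removals)} removed as spikes"
        )
        cleaned.append(ct)

    # --- home ranges and landscape classes --------------------------------
    hr_cfg = config.get("homerange", {})
    levels = tuple(hr_cfg.get("levels", (0.5, 0.95)))
    min_days = float(hr_cfg.get("min_days", MIN_MONITORING_DAYS))
    allow_short = bool(hr_cfg.get("allow_short", False))
    animals: list[dict] = []
    locoh95_list: list[hr.HomeRangeEstimate] = []
    for track in cleaned:
        if strategies.get(track.animal_id, "resident") != "resident":
            log.append(f"{track.animal_id}: non-resident, excluded")
            continue
        if track.duration_days <= min_days and not allow_short:
            log.append(
                f"{track.animal_id}: only {track.duration_days:.0f} days of "
                f"monitoring (needs > {min_days:.0f}), home range skipped"
            )
            continue
        sub = pp.subsample(track)
        pts = sub.points
        a = hr.max_pairwise_distance(pts)
        locoh = hr.alocoh(
            pts, a=a, isopleth_targets=levels,
            animal_id=track.animal_id, coverage_days=sub.duration_days,
        )
        mcp95 = hr.mcp(pts, 95.0, track.animal_id, sub.duration_days)
        mcp50 = hr.mcp(pts, 50.0, track.animal_id, sub.duration_days)
        landcls = hr.classify_landscape(locoh[max(levels)].geometry, raster)
        import warnings as _warnings

        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always")
            comp_hr = hr.complexity_index(mcp95.area_km2, locoh[max(levels)].area_km2)
            comp_core = hr.complexity_index(mcp50.area_km2, locoh[min(levels)].area_km2)
        for wmsg in caught:
            log.append(f"{track.animal_id}: {wmsg.message}")
        animals.append(
            {
                "animal_id": track.animal_id,
                "track": track,
                "n_points": pts.shape[0],
                "coverage_days": sub.duration_days,
                "locoh_hr_km2": locoh[max(levels)].area_km2,
                "locoh_core_km2": locoh[min(levels)].area_km2,
                "mcp_hr_km2": mcp95.area_km2,
                "mcp_core_km2": mcp50.area_km2,
                "complexity_hr": comp_hr,
                "complexity_core": comp_core,
                "n_components_hr": locoh[max(levels)].n_components,
                "landscape": landcls.label,
                "mean_imperviousness": landcls.mean_imperviousness,
            }
        )
        locoh95_list.append(locoh[max(levels)])
    retained = hr.dedup_homeranges(locoh95_list)
    retained_ids = {e.animal_id for e in retained}
    for a_ in animals:
        if a_["animal_id"] not in retained_ids:
            log.append(
                f"{a_['animal_id']}: home range dropped as spatial duplicate "
                "(>90% overlap, less temporal coverage)"
            )
    animals = [a_ for a_ in animals if a_["animal_id"] in retained_ids]

    # --- movement models per landscape class ------------------------------
    hmm_cfg = config.get("hmm", {})
    k_list = list(hmm_cfg.get("n_states", (2, 3, 4)))
    sep = float(hmm_cfg.get("separation_threshold", 2.0))
    class_results: dict[str, dict] = {}
    for cls in sorted({a_["landscape"] for a_ in animals}):
        members = [a_ for a_ in animals if a_["landscape"] == cls]
        bursts = []
        for a_ in members:
            bursts.extend(pp.extract_bursts(a_["track"]))
        if not bursts:
            log.append(f"{cls}: no qualifying bursts, movement model skipped")
            continue
        series = [pp.steps_and_angles(b) for b in bursts]
        fits: dict[int, MovementHMMResults] = {}
        verdicts = {}
        grid_spec = {
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in hmm_cfg.get("start_grid", {}).items()
        }
        for K in k_list:
            model = MovementHMM(series, K)
            grid = build_start_grid(series, K, **grid_spec) if grid_spec else None
            fits[K] = model.fit(start_grid=grid, warn_small=False)
            report = fits[K].plausibility(sep)
            power, strong = fits[K].predictive_power()
            verdicts[K] = {
                "plausible": report.plausible,
                "reasons": report.reasons,
                "predictive_power": power,
                "strong": strong,
                "labels": report.labels,
            }
            log.append(
                f"{cls}: K={K} logL={fits[K].llf:.1f} AIC={fits[K].aic:.1f} "
                f"power={power:.3f} plausible={report.plausible}"
            )
        accepted = [
            K for K in k_list if verdicts[K]["plausible"] and verdicts[K]["strong"]
        ]
        rejected = {
            str(K): (verdicts[K]["reasons"] or ["not strongly predictive"])
            for K in k_list
            if K not in accepted
        }
        result: dict = {"fits": fits, "verdicts": verdicts, "rejected": rejected}
        if accepted:
            best_k = min(accepted, key=lambda K: fits[K].aic)
            best = fits[best_k]
            labels = verdicts[best_k]["labels"]
            # report states ordered by mean step length
            sorted_params, order = best.sorted_params()
            relabel = np.empty(best_k, dtype=int)
            relabel[order] = np.arange(best_k)
            decoded = best.decode(series)
            states = np.concatenate([relabel[d.states - 1] + 1 for d in decoded])
            lengths = np.concatenate([s.lengths for s in series])
            budget = time_budget(
                [states], best_k,
                labels=tuple(np.array(labels, dtype=object)[order]),
            )
            result.update(
                best_k=best_k,
                params=sorted_params,
                decoded_states=states,
                step_lengths=lengths,
                budget=budget,
                labels=budget.labels,
                n_bursts=len(bursts),
                n_individuals=len(members),
            )
            if "foraging" in budget.labels and "traveling" in budget.labels:
                result["ratio"] = foraging_travel_ratio(budget)
            log.append(f"{cls}: accepted {best_k}-state model by AIC")
        else:
            result["best_k"] = None
            log.append(f"{cls}: no plausible and strongly predictive model")
        class_results[cls] = result

    # --- tables and comparisons -------------------------------------------
    space_table, movement_table = summarize_landscape(animals, class_results)
    rep_cfg = config.get("report", {})
    groups = {
        cls: np.array(
            [a_["complexity_hr"] for a_ in animals if a_["landscape"] == cls]
        )
        for cls in sorted({a_["landscape"] for a_ in animals})
    }
    comparisons = {}
    if all(v.size >= 2 for v in groups.values()) and len(groups) >= 2:
        comparisons = compare_groups(
            groups,
            n_permutations=int(rep_cfg.get("n_permutations", 999)),
            seed=seed,
        )

    report = PipelineReport(
        config=config,
        animals=[{k: v for k, v in a_.items() if k != "track"} for a_ in animals],
        class_results=class_results,
        space_table=space_table,
        movement_table=movement_table,
        comparisons=comparisons,
        log=log,
        homerange_estimates=retained,
    )
    if out_dir is not None:
        report.write(out_dir)
    return report
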