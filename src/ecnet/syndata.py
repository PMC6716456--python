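"""Synthetic cohorts with planted directional-network effects.

The generator realizes the study's assumed generative story so that every
downstream stage has ground truth:

* latent neural signals follow a stable first-order VAR whose lag-1
  coupling matrix carries a planted directed chain
  (prefrontal -> insula -> amygdala -> hippocampus -> precuneus-like);
* chain coefficients oscillate over time, with per-group multipliers
  grading both coupling *strength* and coupling *variability*
  (control -> PTSD -> PCS+PTSD);
* observed BOLD-like signals are the latent signals convolved with
  region-specific double-gamma HRFs (jittered time-to-peak) plus noise;
* behavioral scores (PCL5 / NSI / NCI scales) are linear in the subject's
  realized planted multipliers, plus noise.

Matrix orientation convention used throughout the package: coupling
matrices are indexed ``[source, target]``, i.e. ``A1[i, j]`` is the
influence of region ``i`` at time t-1 on region ``j`` at time t.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .types import HRFCurve, ROITimeSeries

GROUPS = ("control", "ptsd", "pcs_ptsd")

OVERFLOW_GUARD = 1e6


# ---------------------------------------------------------------------------
# VAR specification
# ---------------------------------------------------------------------------

@dataclass
class VARSpec:
    """First-order VAR with an optional instantaneous (zero-lag) term.

    Generative model: Z(t) = A0'Z(t) + A1'Z(t-1) + E(t) with
    ``A0[i, j]`` / ``A1[i, j]`` the i -> j couplings.  Stability requires
    the spectral radius of the effective transition A1 (I - A0)^-1 to be
    below 1; the diagonal of A0 is exactly 0 (no instantaneous
    self-coupling, only cross-correlation).
    """

    k: int
    A0: np.ndarray
    A1: np.ndarray
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        self.A0 = np.asarray(self.A0, dtype=float)
        self.A1 = np.asarray(self.A1, dtype=float)
        for name, m in (("A0", self.A0), ("A1", self.A1)):
            if m.shape != (self.k, self.k):
                raise ValueError(f"{name} must be {self.k}x{self.k}")
        if np.any(np.diag(self.A0) != 0):
            raise ValueError("diagonal of A0 must be exactly 0")
        rho = self.spectral_radius()
        if rho >= 1.0:
            raise ValueError(f"unstable VAR spec: spectral radius {rho:.4f} >= 1")

    def spectral_radius(self) -> float:
        trans = self.A1 @ np.linalg.inv(np.eye(self.k) - self.A0)
        return float(np.max(np.abs(np.linalg.eigvals(trans))))


def make_var_spec(
    k: int,
    base_coupling: float = 0.0,
    planted_chain: list[tuple[int, int, float]] | None = None,
    seed: int | None = None,
    self_coupling: float = 0.4,
    noise_sd: float = 1.0,
    backbone_density: float | None = None,
    backbone_weights: tuple[float, float] = (0.2, 0.35),
    n_communities: int = 1,
) -> VARSpec:
    """Build a stable VARSpec with a planted chain in A1.

    ``planted_chain`` is a list of (source, target, weight) triples.
    Background (non-planted off-diagonal) couplings are either small
    dense values drawn from N(0, base_coupling), or — when
    ``backbone_density`` is given — a sparse strong backbone: each
    off-diagonal entry is present with that probability, with weight
    drawn uniformly from ``backbone_weights`` (on top of the dense
    background).  With ``n_communities`` > 1, the backbone is restricted
    to equal contiguous node blocks, so any strong between-community
    links come only from the planted edges (bridge topology).  Raises if
    the result is unstable.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    A1 = np.zeros((k, k))
    if base_coupling:
        A1 = rng.normal(0.0, base_coupling, size=(k, k))
    if backbone_density is not None:
        present = rng.random((k, k)) < backbone_density
        if n_communities > 1:
            block = np.array([min(i * n_communities // k, n_communities - 1)
                              for i in range(k)])
            present &= block[:, None] == block[None, :]
        signs = rng.choice([-1.0, 1.0], size=(k, k))  # sign cancellation keeps the VAR stable
        A1 = np.where(present, signs * rng.uniform(*backbone_weights, size=(k, k)), A1)
    np.fill_diagonal(A1, self_coupling)
    for src, tgt, w in planted_chain or []:
        if abs(w) >= 1:
            raise ValueError("coupling magnitudes must be < 1")
        A1[src, tgt] = w
    return VARSpec(k=k, A0=np.zeros((k, k)), A1=A1, noise_sd=noise_sd)


# ---------------------------------------------------------------------------
# Time-varying coupling schedule
# ---------------------------------------------------------------------------

@dataclass
class EdgeModulation:
    """Coefficient trajectory for one directed edge.

    ``kind='sine'``: value(t) = mean + amplitude*sin(2*pi*t/period + phase)
    ``kind='square'``: mean + amplitude*sign(sin(2*pi*t/period + phase))
    (metastable state-switching between a weak and a strong coupling regime)
    ``kind='step'``: value(t) = before for t < switch_t else after
    The trajectory *replaces* the static A1 entry at every t.
    """

    source: int
    target: int
    kind: str = "sine"
    mean: float = 0.0
    amplitude: float = 0.0
    period: float = 100.0
    phase: float = 0.0
    before: float = 0.0
    after: float = 0.0
    switch_t: int = 0

    def values(self, T: int) -> np.ndarray:
        t = np.arange(T)
        if self.kind == "sine":
            return self.mean + self.amplitude * np.sin(2 * np.pi * t / self.period + self.phase)
        if self.kind == "square":
            return self.mean + self.amplitude * np.sign(
                np.sin(2 * np.pi * t / self.period + self.phase))
        if self.kind == "step":
            return np.where(t < self.switch_t, self.before, self.after)
        if self.kind == "constant":
            return np.full(T, self.mean)
        raise ValueError(f"unknown modulation kind {self.kind!r}")


@dataclass
class DynamicSchedule:
    """Collection of per-edge coefficient trajectories."""

    modulations: list[EdgeModulation] = field(default_factory=list)

    @property
    def edges(self) -> list[tuple[int, int]]:
        return [(m.source, m.target) for m in self.modulations]

    def coefficient_matrix(self, spec: VARSpec, T: int) -> np.ndarray:
        """Materialize A1(t) as a (T, k, k) array."""
        A1t = np.broadcast_to(spec.A1, (T, spec.k, spec.k)).copy()
        for m in self.modulations:
            A1t[:, m.source, m.target] = m.values(T)
        return A1t

    def check_stability(self, spec: VARSpec, T: int, n_probe: int = 32) -> None:
        """Verify spectral radius < 1 on a probe grid of timepoints."""
        A1t = self.coefficient_matrix(spec, T)
        inv0 = np.linalg.inv(np.eye(spec.k) - spec.A0)
        probes = np.unique(np.linspace(0, T - 1, n_probe).astype(int))
        for t in probes:
            rho = float(np.max(np.abs(np.linalg.eigvals(A1t[t] @ inv0))))
            if rho >= 1.0:
                raise ValueError(f"scheduled coupling unstable at t={t}: spectral radius {rho:.4f}")


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate_neural(
    spec: VARSpec,
    schedule: DynamicSchedule | None,
    T: int,
    seed: int | None = None,
    tr: float = 1.0,
    burn: int = 100,
) -> ROITimeSeries:
    """Simulate latent neural signals from the (time-varying) VAR.

    A ``burn`` prefix is simulated and discarded so the retained segment
    starts near stationarity.  Divergence past the overflow guard
    (|Z| > 1e6) raises, naming the first bad timepoint.
    """
    if T < 10 * spec.k:
        raise ValueError(f"T={T} too short; need at least 10*k={10 * spec.k}")
    rng = np.random.default_rng(seed)
    total = T + burn
    schedule = schedule or DynamicSchedule()
    if schedule.modulations:
        schedule.check_stability(spec, T)
    # schedule trajectories are defined on the retained segment; the burn-in
    # prefix uses the trajectory value at t=0
    A1t = schedule.coefficient_matrix(spec, T) if schedule.modulations else None
    inv0 = np.linalg.inv(np.eye(spec.k) - spec.A0)
    z = np.zeros(spec.k)
    out = np.empty((total, spec.k))
    noise = rng.normal(0.0, spec.noise_sd, size=(total, spec.k))
    for t in range(total):
        if A1t is None:
            a1 = spec.A1
        else:
            a1 = A1t[max(0, t - burn)]
        z = (z @ a1 + noise[t]) @ inv0
        if np.max(np.abs(z)) > OVERFLOW_GUARD:
            raise FloatingPointError(f"simulation diverged at t={t - burn} (|Z| > {OVERFLOW_GUARD:g})")
        out[t] = z
    return ROITimeSeries(out[burn:], tr=tr)


# ---------------------------------------------------------------------------
# Hemodynamics
# ---------------------------------------------------------------------------

def hrf_double_gamma(
    peak_time: float = 6.0,
    undershoot_time: float = 16.0,
    ratio: float = 1.0 / 6.0,
    dt: float = 0.5,
    duration: float = 24.0,
) -> HRFCurve:
    """Canonical double-gamma HRF, peak-normalized.

    Gamma densities with unit scale; shape a = time + 1 puts the mode of
    each lobe at ``peak_time`` / ``undershoot_time`` seconds.
    """
    from scipy import stats

    if not (0 < dt <= peak_time < duration):
        raise ValueError("require 0 < dt <= peak_time < duration")
    t = np.arange(0.0, duration, dt)
    h = stats.gamma.pdf(t, peak_time + 1.0) - ratio * stats.gamma.pdf(t, undershoot_time + 1.0)
    return HRFCurve(samples=h / np.max(h), dt=dt, peak_time=float(t[np.argmax(h)]))


def convolve_bold(
    neural: ROITimeSeries,
    hrfs: list[HRFCurve],
    obs_noise_sd: float = 0.0,
    seed: int | None = None,
) -> ROITimeSeries:
    """Causal convolution of each region with its HRF plus Gaussian noise.

    The convolution tail is truncated so the output keeps length T.
    """
    if len(hrfs) != neural.n_regions:
        raise ValueError("one HRFCurve per region required")
    rng = np.random.default_rng(seed)
    T = neural.n_timepoints
    out = np.empty_like(neural.data)
    for j, h in enumerate(hrfs):
        if not np.isclose(h.dt, neural.tr):
            raise ValueError(f"HRF dt ({h.dt}) must equal TR ({neural.tr}) for region {j}")
        out[:, j] = np.convolve(neural.data[:, j], h.samples)[:T]
    if obs_noise_sd > 0:
        out = out + rng.normal(0.0, obs_noise_sd, size=out.shape)
    return ROITimeSeries(out, tr=neural.tr, labels=list(neural.labels))


def lagged_hrf_pair(
    T: int = 2000,
    tr: float = 2.0,
    n_events: int = 240,
    peak_times: tuple[float, float] = (5.0, 7.0),
    obs_noise_frac: float = 0.15,
    seed: int | None = None,
) -> tuple[ROITimeSeries, ROITimeSeries]:
    """Spurious-causality construction: one neural signal, two lagged HRFs.

    Both regions share an identical point-process neural signal (random
    events with variable amplitude); their HRFs differ only in
    time-to-peak.  The BOLD pair then shows strong directed coupling from
    the early-peaking to the late-peaking region even though the latent
    signals are perfectly synchronous — the confound hemodynamic
    deconvolution is meant to remove.  Returns (bold, neural).
    """
    rng = np.random.default_rng(seed)
    ev = np.sort(rng.choice(np.arange(5, T - 5), n_events, replace=False))
    x = np.zeros(T)
    x[ev] = rng.uniform(0.5, 1.5, n_events)
    neural = ROITimeSeries(np.column_stack([x, x]), tr=tr)
    hrfs = [hrf_double_gamma(pt, pt + 10.0, dt=tr) for pt in peak_times]
    scale = float(np.convolve(x, hrfs[0].samples)[:T].std())
    bold = convolve_bold(neural, hrfs, obs_noise_sd=obs_noise_frac * scale,
                         seed=int(rng.integers(0, 2**31 - 1)))
    return bold, neural


# ---------------------------------------------------------------------------
# Cohort design
# ---------------------------------------------------------------------------

@dataclass
class PlantedEdge:
    """One planted directed edge with per-group effect multipliers.

    ``strength_multipliers`` scale the static coupling coefficient per
    group (monotone control -> ptsd -> pcs_ptsd; increasing = inflation,
    decreasing = deflation).  ``variability_multipliers`` scale the
    amplitude of the sinusoidal coefficient oscillation (control strictly
    greatest, then non-increasing: clinical rigidity).
    """

    source: int
    target: int
    base_weight: float = 0.35
    strength_multipliers: tuple[float, float, float] = (1.0, 1.0, 1.0)
    variability_multipliers: tuple[float, float, float] = (1.0, 1.0, 1.0)
    mod_amplitude: float = 0.35
    mod_period: float = 125.0
    mod_kind: str = "square"
    mod_baseline: str = "floor"   # "floor": oscillate up from base; "center": around base

    def __post_init__(self) -> None:
        s = self.strength_multipliers
        if not (s[0] <= s[1] <= s[2] or s[0] >= s[1] >= s[2]):
            raise ValueError(f"strength multipliers must be monotone across groups: {s}")
        v = self.variability_multipliers
        if not (v[0] > v[1] >= v[2]) and not (v[0] == v[1] == v[2]):
            raise ValueError(
                "variability multipliers must have control strictly greatest then non-increasing "
                f"(or be flat): {v}"
            )


@dataclass
class BehaviorModel:
    """Linear map from a subject's realized planted multipliers to a score.

    score = intercept + strength_weight * mean(strength multipliers)
            + variability_weight * mean(variability multipliers) + N(0, noise_sd)
    """

    name: str
    intercept: float
    strength_weight: float = 0.0
    variability_weight: float = 0.0
    noise_sd: float = 0.0


def default_planted_chain() -> list[PlantedEdge]:
    """Planted 4-edge chain over regions 0..4 with a hypothesis-2 signature.

    Chain coupling bursts upward from a common floor (square-wave state
    switching); pathology shrinks the burst amplitude, so mean coupling
    strength and coupling variability deflate together — the
    deflation-plus-rigidity co-occurrence the framework is built to
    detect — strictly graded control > ptsd > pcs_ptsd.
    """
    rigid = (1.0, 0.5, 0.03)
    return [
        PlantedEdge(i, i + 1, base_weight=0.35, strength_multipliers=(1.0, 1.0, 1.0),
                    variability_multipliers=rigid, mod_amplitude=0.30,
                    mod_period=250.0, mod_kind="square")
        for i in range(4)
    ]


def default_reference_edge() -> PlantedEdge:
    """Strong constant edge anchoring per-graph max-normalization.

    Without a stable strongest connection, dividing every graph by its
    own maximum would cancel uniform planted strength changes.
    """
    return PlantedEdge(6, 7, base_weight=0.97, strength_multipliers=(1.0, 1.0, 1.0),
                       variability_multipliers=(1.0, 1.0, 1.0), mod_amplitude=0.0,
                       mod_kind="constant")


def default_h1_edges() -> list[PlantedEdge]:
    """Two edges altered in both clinical groups but not between them."""
    return [
        PlantedEdge(5, 15, base_weight=0.35, strength_multipliers=(1.0, 1.0, 1.0),
                    variability_multipliers=(1.0, 0.45, 0.45), mod_amplitude=0.28,
                    mod_period=250.0, mod_kind="square"),
        PlantedEdge(7, 16, base_weight=0.35, strength_multipliers=(1.0, 1.0, 1.0),
                    variability_multipliers=(1.0, 0.45, 0.45), mod_amplitude=0.28,
                    mod_period=250.0, mod_kind="square"),
    ]


def default_diffuse_edges(seed: int = 123, n_edges: int = 12) -> list[PlantedEdge]:
    """Diffuse pathology outside the scored chain.

    The disorder affects many connections, not just the chain; these
    edges share the hypothesis-2 signature (graded burst loss) on an
    acyclic bipartite block (8..13 -> 14..19) and keep the multiple-
    comparison landscape realistic.
    """
    rng = np.random.default_rng(seed)
    pool = [(a, b) for a in range(8, 14) for b in range(14, 20)]
    picks = rng.choice(len(pool), size=n_edges, replace=False)
    out = []
    for pi in picks:
        a, b = pool[pi]
        vc = float(rng.uniform(0.35, 0.55))
        out.append(PlantedEdge(a, b, base_weight=float(rng.uniform(0.3, 0.4)),
                               strength_multipliers=(1.0, 1.0, 1.0),
                               variability_multipliers=(1.0, vc, vc * vc),
                               mod_amplitude=float(rng.uniform(0.2, 0.28)),
                               mod_period=250.0, mod_kind="square"))
    return out


def default_planted_network() -> list[PlantedEdge]:
    """Chain + reference anchor + hypothesis-1 edges + diffuse pathology."""
    return (default_planted_chain() + [default_reference_edge()]
            + default_h1_edges() + default_diffuse_edges())


def default_behavior_models() -> list[BehaviorModel]:
    # variability multipliers fall with pathology, so symptom scales load
    # negatively on them (controls ~ low PCL5/NSI, high NCI)
    return [
        BehaviorModel("PCL5", intercept=65.0, variability_weight=-45.0, noise_sd=4.0),
        BehaviorModel("NSI", intercept=50.0, variability_weight=-40.0, noise_sd=4.0),
        BehaviorModel("NCI", intercept=72.0, variability_weight=35.0, noise_sd=5.0),
    ]


@dataclass
class CohortDesign:
    """Full specification of a synthetic three-group cohort."""

    n_per_group: tuple[int, int, int] = (20, 20, 20)
    k: int = 20
    T: int = 500
    tr: float = 1.0
    planted_chain: list[PlantedEdge] = field(default_factory=default_planted_network)
    background_coupling: float = 0.09
    backbone_density: float | None = None
    backbone_weights: tuple[float, float] = (0.2, 0.35)
    n_communities: int = 1
    self_coupling: float = 0.3
    noise_sd: float = 1.0
    subject_jitter_sd: float = 0.02
    behavior_models: list[BehaviorModel] = field(default_factory=default_behavior_models)
    shared_background: bool = True    # one anatomical backbone for the cohort
    hrf_confound: bool = False
    hrf_peak_range: tuple[float, float] = (4.5, 7.5)
    obs_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_group) != 3:
            raise ValueError("n_per_group must give counts for the 3 groups")
        if self.k < max((max(e.source, e.target) for e in self.planted_chain), default=1) + 1:
            raise ValueError("k too small for the planted edges")


@dataclass
class Subject:
    subject_id: str
    group: str
    ts: ROITimeSeries
    latent: ROITimeSeries


@dataclass
class Cohort:
    design: CohortDesign | None
    subjects: list[Subject]
    manifest: pd.DataFrame
    ground_truth: dict


def _subject_schedule(
    design: CohortDesign, gi: int, rng: np.random.Generator
) -> tuple[DynamicSchedule, dict]:
    """Draw one subject's planted multipliers and coupling schedule."""
    mods, realized = [], {}
    for e in design.planted_chain:
        s = e.strength_multipliers[gi] * (1.0 + rng.normal(0.0, design.subject_jitter_sd))
        v = max(0.0, e.variability_multipliers[gi] * (1.0 + rng.normal(0.0, design.subject_jitter_sd)))
        amp = e.mod_amplitude * v
        # "floor" baseline: coupling bursts upward from a stable floor, so
        # losing burst amplitude lowers mean strength and variability together
        mean = e.base_weight * s + (amp if e.mod_baseline == "floor" else 0.0)
        mods.append(EdgeModulation(e.source, e.target, kind=e.mod_kind, mean=mean,
                                   amplitude=amp, period=e.mod_period,
                                   phase=rng.uniform(0, 2 * np.pi)))
        realized[f"{e.source}>{e.target}"] = {
            "strength_multiplier": s,
            "variability_multiplier": v,
            "coefficient_mean": mean,
            "coefficient_amplitude": amp,
            # variance of a square wave is a^2; of a sinusoid a^2/2
            "generative_dgc_variance": amp * amp * (1.0 if e.mod_kind == "square" else 0.5),
        }
    return DynamicSchedule(mods), realized


def simulate_cohort(design: CohortDesign, out_dir: str | Path | None = None) -> Cohort:
    """Simulate a full cohort; optionally write delimited-text outputs.

    Per subject: a background VAR spec, group-graded planted-edge
    schedule (5 stability attempts with fresh jitter, then fail),
    simulation, optional HRF convolution, and behavioral scores linear in
    the realized multipliers.  Deterministic given ``design.seed``.
    """
    master = np.random.default_rng(design.seed)
    background_seed = int(master.integers(0, 2**31 - 1))
    subjects: list[Subject] = []
    rows = []
    truth_subjects = {}
    sid = 0
    for gi, group in enumerate(GROUPS):
        for _ in range(design.n_per_group[gi]):
            subject_id = f"sub-{sid:03d}"
            rng = np.random.default_rng(master.integers(0, 2**31 - 1))
            spec = make_var_spec(
                design.k,
                base_coupling=design.background_coupling,
                seed=background_seed if design.shared_background
                else int(rng.integers(0, 2**31 - 1)),
                self_coupling=design.self_coupling,
                noise_sd=design.noise_sd,
                backbone_density=design.backbone_density,
                backbone_weights=design.backbone_weights,
                n_communities=design.n_communities,
            )
            latent = None
            for _attempt in range(5):
                try:
                    schedule, realized = _subject_schedule(design, gi, rng)
                    latent = simulate_neural(spec, schedule, design.T,
                                             seed=int(rng.integers(0, 2**31 - 1)),
                                             tr=design.tr)
                    break
                except (ValueError, FloatingPointError):
                    continue
            if latent is None:
                raise RuntimeError(f"could not draw a stable spec for {subject_id} in 5 attempts")

            if design.hrf_confound:
                hrfs = [
                    hrf_double_gamma(peak_time=float(rng.uniform(*design.hrf_peak_range)),
                                     dt=design.tr)
                    for _ in range(design.k)
                ]
                ts = convolve_bold(latent, hrfs, obs_noise_sd=design.obs_noise_sd,
                                   seed=int(rng.integers(0, 2**31 - 1)))
            else:
                noisy = latent.data + rng.normal(0.0, design.obs_noise_sd, size=latent.data.shape)
                ts = ROITimeSeries(noisy, tr=design.tr, labels=list(latent.labels))

            mean_s = float(np.mean([r["strength_multiplier"] for r in realized.values()]))
            mean_v = float(np.mean([r["variability_multiplier"] for r in realized.values()]))
            scores = {
                b.name: b.intercept + b.strength_weight * mean_s
                + b.variability_weight * mean_v + rng.normal(0.0, b.noise_sd)
                for b in design.behavior_models
            }
            row = {
                "subject": subject_id,
                "group": group,
                "age": float(np.round(rng.normal(32.0, 6.0), 1)),
                "education": float(np.round(np.clip(rng.normal(14.0, 2.0), 8, 22), 1)),
                "race": str(rng.choice(["groupA", "groupB", "groupC"], p=[0.5, 0.3, 0.2])),
                "motion": float(np.round(rng.lognormal(-2.3, 0.4), 4)),
            }
            row.update({k: float(np.round(v, 2)) for k, v in scores.items()})
            rows.append(row)
            truth_subjects[subject_id] = {"group": group, "edges": realized}
            subjects.append(Subject(subject_id, group, ts, latent))
            sid += 1

    manifest = pd.DataFrame(rows)
    ground_truth = {
        "planted_edges": [
            {
                "source": e.source,
                "target": e.target,
                "edge": f"{e.source}>{e.target}",
                "base_weight": e.base_weight,
                "strength_multipliers": list(e.strength_multipliers),
                "variability_multipliers": list(e.variability_multipliers),
                "mod_amplitude": e.mod_amplitude,
                "mod_period": e.mod_period,
            }
            for e in design.planted_chain
        ],
        "subjects": truth_subjects,
    }
    cohort = Cohort(design, subjects, manifest, ground_truth)
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def load_cohort(in_dir: str | Path, tr: float = 1.0) -> Cohort:
    """Read a cohort written by :func:`write_cohort` back from delimited text."""
    src = Path(in_dir)
    manifest = pd.read_csv(src / "manifest.tsv", sep="\t")
    ground_truth = json.loads((src / "ground_truth.json").read_text())
    subjects = []
    for _, row in manifest.iterrows():
        df = pd.read_csv(src / f"{row['subject']}_ts.tsv", sep="\t")
        ts = ROITimeSeries(df.to_numpy(), tr=tr, labels=list(df.columns))
        subjects.append(Subject(row["subject"], row["group"], ts, ts))
    return Cohort(design=None, subjects=subjects, manifest=manifest,
                  ground_truth=ground_truth)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in cohort.subjects:
        df = pd.DataFrame(s.ts.data, columns=s.ts.labels)
        df.to_csv(out / f"{s.subject_id}_ts.tsv", sep="\t", index=False, float_format="%.6f")
    cohort.manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    (out / "ground_truth.json").write_text(json.dumps(cohort.ground_truth, indent=1))
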