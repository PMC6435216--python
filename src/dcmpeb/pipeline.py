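"""End-to-end orchestration of the three-level connectivity analysis.

One configuration object drives the whole chain: data (synthetic cohort
or EDF recordings) -> per-window cross-spectral features -> per-window
model inversion (optionally refined under empirical shrinkage priors)
-> per-subject PEB over temporal basis functions, per connection type
-> model-space scoring and fixed-effects pooling over subjects ->
group PEB with greedy pruning and model averaging -> predicted
trajectories with credible bands.  All randomness flows from one master
seed; window inversions are independent work units, so execution order
never changes results.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .beliefs import GaussianBelief
from .design import DesignMatrix, build_design
from .features import CrossSpectralData, mar_csd, project_modes, read_edf, segment_windows
from .inversion import DCMPosterior, peb_fit
from .networks import EDGE_TYPES, NetworkSpec, build_network
from .nmm import default_priors
from .peb import (
    BMAResult,
    ModelSpace,
    PEBResult,
    Trajectories,
    bmc_over_subjects,
    enumerate_reduced_models,
    greedy_search_bma,
    group_peb,
    peb_estimate,
    predict_trajectories,
    score_reduced_models,
)
from .synthetic import GroundTruth, SyntheticDataset, default_ground_truth, simulate_group

__all__ = ["PipelineConfig", "ResultsBundle", "run_pipeline", "split_half", "prepare_windows"]


@dataclass
class PipelineConfig:
    """Settings for one pipeline run.

    Synthetic runs need only `network`, sizes and the ground-truth
    effect settings; file runs list EDF paths in `edf_paths`.
    """

    network: str = "chain2"
    win_s: float = 1.0
    band: tuple[float, float] = (1.0, 45.0)
    freq_step: float = 4.0
    freq_start: float = 4.0
    freq_stop: float = 40.0
    n_modes: int = 0  # 0 -> one mode per source
    dct_orders: tuple[int, ...] = (2, 3, 4)
    decay_tau: float = 16.0
    seed: int = 0
    outdir: str | None = None
    # first level
    refine_iters: int = 2  # outer empirical-shrinkage rounds (1 = independent inversions)
    max_vl_iter: int = 64
    # synthetic cohort
    n_subjects: int = 2
    n_windows: int = 10
    decay_effect: float = -0.4
    dct_dispersion: float = 0.2
    window_noise_sd: float = 0.05
    obs_noise_sd: float = 0.02
    # real data
    edf_paths: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.decay_tau <= 0:
            raise ValueError("decay constant must be positive")
        if self.win_s <= 0:
            raise ValueError("window length must be positive")

    @property
    def freqs(self) -> np.ndarray:
        return np.arange(self.freq_start, self.freq_stop + 1e-9, self.freq_step)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as f:
            doc = yaml.safe_load(f) or {}
        for key in ("band", "dct_orders"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)

    def to_yaml(self, path: str) -> None:
        doc = asdict(self)
        doc["band"] = list(self.band)
        doc["dct_orders"] = list(self.dct_orders)
        with open(path, "w") as f:
            yaml.safe_dump(doc, f, sort_keys=False)

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclass
class GroupResult:
    """Group-level outcome for one connection type."""

    model_space: ModelSpace
    group: PEBResult
    bma: BMAResult
    trajectories: Trajectories


@dataclass
class ResultsBundle:
    """Everything one pipeline run produces, hash-linked for provenance."""

    config: PipelineConfig
    spec: NetworkSpec
    design: DesignMatrix
    gain: np.ndarray
    window_posteriors: list[list[DCMPosterior]]  # per subject
    subject_pebs: dict[str, list[PEBResult]]  # per connection type
    groups: dict[str, GroupResult]
    diagnostics: pd.DataFrame
    provenance: dict[str, str] = field(default_factory=dict)
    truth: GroundTruth | None = None
    empirical_priors: list[GaussianBelief] | None = None  # per-subject first-level priors

    def pooled_logev(self, conn_type: str) -> np.ndarray:
        return self.groups[conn_type].model_space.pooled_logev

    def save(self, outdir: str) -> None:
        """Persist the exportable tables, design and provenance as text/CSV."""
        os.makedirs(outdir, exist_ok=True)
        self.config.to_yaml(os.path.join(outdir, "config.yaml"))
        with open(os.path.join(outdir, "network.yaml"), "w") as f:
            f.write(self.spec.to_yaml())
        with open(os.path.join(outdir, "design.tsv"), "w") as f:
            f.write(self.design.to_text())
        self.diagnostics.to_csv(os.path.join(outdir, "diagnostics.csv"), index=False)
        for t, g in self.groups.items():
            g.model_space.to_frame().to_csv(os.path.join(outdir, f"model_space_{t}.csv"), index=False)
            g.bma.to_frame().to_csv(os.path.join(outdir, f"bma_{t}.csv"), index=False)
            traj = pd.DataFrame(g.trajectories.values, columns=g.trajectories.connection_labels)
            traj.to_csv(os.path.join(outdir, f"trajectories_{t}.csv"), index=False)
        for s, posts in enumerate(self.window_posteriors):
            np.savez_compressed(
                os.path.join(outdir, f"posteriors_s{s:03d}.npz"),
                means=np.stack([d.belief.mean for d in posts]),
                covs=np.stack([d.belief.cov for d in posts]),
                F=np.array([d.F for d in posts]),
                explained_variance=np.array([d.explained_variance for d in posts]),
                log_precision=np.array([d.log_precision for d in posts]),
                seed=self.config.seed,
            )
        with open(os.path.join(outdir, "provenance.json"), "w") as f:
            json.dump(self.provenance, f, indent=2)


def _sha(*arrays: np.ndarray) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]


def prepare_windows(config: PipelineConfig) -> tuple[NetworkSpec, np.ndarray, list[list[CrossSpectralData]], GroundTruth | None]:
    """Stage 1: produce per-subject window CSD lists (synthetic or EDF)."""
    spec = build_network(config.network, n_modes=config.n_modes)
    freqs = config.freqs
    if freqs.min() < config.band[0] or freqs.max() > config.band[1]:
        raise ValueError("frequency grid outside the analysis band")
    if config.edf_paths:
        subjects = []
        gain = None
        for path in config.edf_paths:
            series, fs = read_edf(path)
            if series.shape[1] < fs * config.win_s:
                raise ValueError(f"{path}: window length {config.win_s}s exceeds recording")
            modes, _ = project_modes(series, spec.n_modes)
            wins = segment_windows(modes, fs, config.win_s)
            subjects.append([mar_csd(w, freqs=freqs, fs=fs, window_index=i) for i, w in enumerate(wins)])
        from .synthetic import random_gain

        gain = random_gain(spec.n_modes, spec.n_sources, seed=config.seed)
        return spec, gain, subjects, None
    truth = default_ground_truth(
        spec,
        n_windows=config.n_windows,
        decay_effect=config.decay_effect,
        dct_dispersion=config.dct_dispersion,
        seed=config.seed,
        window_noise_sd=config.window_noise_sd,
        obs_noise_sd=config.obs_noise_sd,
        freqs=freqs,
    )
    dataset: SyntheticDataset = simulate_group(truth, config.n_subjects, seed=config.seed)
    return spec, dataset.gain, [s.windows for s in dataset.subjects], truth


def _present_types(spec: NetworkSpec) -> list[str]:
    return [t for t in EDGE_TYPES if spec.edge_indices(t)]


def group_stages(
    spec: NetworkSpec,
    design: DesignMatrix,
    posteriors: list[list[DCMPosterior]],
    prior: GaussianBelief,
    subject_idx: list[int] | None = None,
    bmr_priors: list[GaussianBelief] | None = None,
) -> tuple[dict[str, list[PEBResult]], dict[str, GroupResult]]:
    """Stages 3-6: per-subject PEB, BMC pooling, group PEB, BMA, trajectories."""
    idx = list(range(len(posteriors))) if subject_idx is None else list(subject_idx)
    subject_pebs: dict[str, list[PEBResult]] = {}
    groups: dict[str, GroupResult] = {}
    for t in _present_types(spec):
        pebs = []
        for s in idx:
            beliefs = [d.belief for d in posteriors[s]]
            ref = bmr_priors[s] if bmr_priors is not None else None
            pebs.append(peb_estimate(beliefs, prior, design, field_sel=t, spec=spec, bmr_prior=ref))
        subject_pebs[t] = pebs
        scaffold = enumerate_reduced_models(design.P - 1, design.optional_labels)
        lev = np.array([score_reduced_models(p, scaffold) for p in pebs])
        space = bmc_over_subjects(lev, scaffold)
        g = group_peb(pebs)
        bma = greedy_search_bma(g)
        traj = predict_trajectories(bma, design)
        groups[t] = GroupResult(model_space=space, group=g, bma=bma, trajectories=traj)
    return subject_pebs, groups


def run_pipeline(config: PipelineConfig) -> ResultsBundle:
    """Execute the full hierarchy and return (optionally save) the bundle."""
    spec, gain, subjects, truth = prepare_windows(config)
    W = len(subjects[0])
    design = build_design(W, dct_orders=config.dct_orders, decay_tau=config.decay_tau)
    prior = default_priors(spec)
    provenance = {"config": config.digest(), "gain": _sha(gain)}

    posteriors: list[list[DCMPosterior]] = []
    emp_priors: list[GaussianBelief] = []
    for s, wins in enumerate(subjects):
        posts, emp = peb_fit(
            wins, spec, prior, gain, max_iter=config.refine_iters, vl_max_iter=config.max_vl_iter, return_prior=True
        )
        posteriors.append(posts)
        emp_priors.append(emp)
    provenance["first_level"] = _sha(*[d.belief.mean for posts in posteriors for d in posts])

    subject_pebs, groups = group_stages(spec, design, posteriors, prior, bmr_priors=emp_priors)
    provenance["group"] = _sha(*[g.bma.mean for g in groups.values()])

    diag = pd.DataFrame(
        [
            {"subject": s, "window": d.window, "explained_variance": d.explained_variance, "F": d.F}
            for s, posts in enumerate(posteriors)
            for d in posts
        ]
    )
    bundle = ResultsBundle(
        config=config,
        spec=spec,
        design=design,
        gain=gain,
        window_posteriors=posteriors,
        subject_pebs=subject_pebs,
        groups=groups,
        diagnostics=diag,
        provenance=provenance,
        truth=truth,
        empirical_priors=emp_priors,
    )
    if config.outdir:
        bundle.save(config.outdir)
    return bundle


def split_half(bundle: ResultsBundle, seed: int = 0) -> tuple[ResultsBundle, ResultsBundle]:
    """Robustness check: redo the group-level analysis on two random halves.

    First-level posteriors are shared (windows are inverted once); the
    cohort is partitioned into two near-equal subgroups by a seeded
    permutation and the pooling, group PEB, pruning and averaging are
    repeated within each half.
    """
    n = len(bundle.window_posteriors)
    if n < 2:
        raise ValueError("split-half needs at least 2 subjects")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    halves = [sorted(perm[: (n + 1) // 2].tolist()), sorted(perm[(n + 1) // 2 :].tolist())]
    prior = default_priors(bundle.spec)
    out = []
    for half in halves:
        pebs, groups = group_stages(
            bundle.spec,
            bundle.design,
            bundle.window_posteriors,
            prior,
            subject_idx=half,
            bmr_priors=bundle.empirical_priors,
        )
        out.append(
            ResultsBundle(
                config=bundle.config,
                spec=bundle.spec,
                design=bundle.design,
                gain=bundle.gain,
                window_posteriors=[bundle.window_posteriors[s] for s in half],
                subject_pebs=pebs,
                groups=groups,
                diagnostics=bundle.diagnostics[bundle.diagnostics.subject.isin(half)].reset_index(drop=True),
                provenance={**bundle.provenance, "split": f"{half}"},
                truth=bundle.truth,
                empirical_priors=None
                if bundle.empirical_priors is None
                else [bundle.empirical_priors[s] for s in half],
            )
        )
    return out[0], out[1]
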