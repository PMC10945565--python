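"""Config-driven workflows: burst detection, dynamic network analysis,
static network analysis.

A pipeline is described by a plain dict (usually loaded from YAML) and
executed end to end: data preparation, training an ensemble of N runs
and keeping the lowest-free-energy one, dual estimation, spectral
estimation, summary statistics and (optionally) group inference.  Every
numeric artifact plus a provenance record (config, seeds, free
energies) is written to the output directory.

Because training starts from random parameters and uses stochastic
updates, independent runs can converge to different local optima; the
run with the lowest variational free energy is kept
(:func:`select_best_run`), and :func:`align_states` matches states or
modes across runs (by maximal covariance correlation, solved as a
linear assignment) so that results can be compared between independent
ensembles for reproducibility checks.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment

from . import prepare as prep
from . import spectra as spec
from . import summary as summ
from .data import PreparedData, TimeSeriesSet
from .dynemo import DyNeMo, DyNeMoResults
from .hmm import GaussianHMM, HMMResults

__all__ = [
    "PipelineConfig",
    "RunEnsemble",
    "fit_ensemble",
    "select_best_run",
    "align_states",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

PIPELINE_KINDS = ("burst", "dynamic_network", "static")


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    """Validated pipeline description (see README for the YAML schema)."""

    kind: str
    preparation: dict
    model: dict
    spectra: dict
    group: dict
    seed: int
    output_dir: str

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kind = d.get("kind")
        if kind not in PIPELINE_KINDS:
            raise ConfigError(f"kind must be one of {PIPELINE_KINDS}, got {kind!r}")
        model = dict(d.get("model", {}))
        if kind != "static":
            if model.get("type") not in ("hmm", "dynemo"):
                raise ConfigError("model.type must be 'hmm' or 'dynemo'")
            if "n_states" not in model:
                raise ConfigError("model.n_states (K for hmm, J for dynemo) is required")
        return cls(
            kind=kind,
            preparation=dict(d.get("preparation", {})),
            model=model,
            spectra=dict(d.get("spectra", {})),
            group=dict(d.get("group", {})),
            seed=int(d.get("seed", 0)),
            output_dir=str(d.get("output_dir", "statedyn_output")),
        )

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "preparation": self.preparation,
            "model": self.model,
            "spectra": self.spectra,
            "group": self.group,
            "seed": self.seed,
            "output_dir": self.output_dir,
        }


# ---------------------------------------------------------------------------
# ensembles


@dataclass
class RunEnsemble:
    """N independently trained models plus their free energies."""

    results: list
    free_energies: np.ndarray

    def __post_init__(self):
        if len(self.results) == 0:
            raise ValueError("all runs failed: the ensemble is empty")
        self.free_energies = np.asarray(self.free_energies, dtype=float)

    @property
    def best_index(self) -> int:
        # ties broken by earliest run index (argmin returns the first)
        return int(np.argmin(self.free_energies))


def fit_ensemble(
    model_factory, n_runs: int, seed: int = 0, fit_kwargs: dict | None = None
) -> RunEnsemble:
    """Train ``n_runs`` independent models; run r uses seed ``seed + r``."""
    fit_kwargs = dict(fit_kwargs or {})
    results, fes = [], []
    for r in range(n_runs):
        model = model_factory()
        res = model.fit(seed=seed + r, **fit_kwargs)
        results.append(res)
        fes.append(res.free_energy)
        logger.info("run %d/%d free energy %.4f", r + 1, n_runs, res.free_energy)
    return RunEnsemble(results=results, free_energies=np.array(fes))


def select_best_run(ensemble: RunEnsemble):
    """The model with the lowest variational free energy."""
    return ensemble.results[ensemble.best_index]


def _covariances_of(obj) -> np.ndarray:
    if isinstance(obj, HMMResults):
        return obj.params.covariances
    if isinstance(obj, DyNeMoResults):
        return obj.params.mode_covariances
    if hasattr(obj, "covariances"):
        return obj.covariances
    if hasattr(obj, "mode_covariances"):
        return obj.mode_covariances
    return np.asarray(obj)


def align_states(model_a, model_b) -> np.ndarray:
    """Permutation ``perm`` such that state ``perm[k]`` of model_b matches
    state k of model_a, maximizing the total Pearson correlation between
    the (flattened) state/mode covariances."""
    ca = _covariances_of(model_a)
    cb = _covariances_of(model_b)
    if ca.shape != cb.shape:
        raise ValueError("models must have the same number of states and channels")
    K = ca.shape[0]
    corr = np.empty((K, K))
    for i in range(K):
        for j in range(K):
            corr[i, j] = np.corrcoef(ca[i].ravel(), cb[j].ravel())[0, 1]
    _, perm = linear_sum_assignment(-corr)
    return perm


# ---------------------------------------------------------------------------
# pipeline execution


def _save_csv(path: Path, array: np.ndarray, fmt="%.10g"):
    np.savetxt(path, np.atleast_2d(array), delimiter=",", fmt=fmt)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

        return wrapped

    return deco


@_stage("prepare")
def _run_prepare(config: PipelineConfig, ts: TimeSeriesSet) -> PreparedData:
    p = config.preparation
    method = p.get("method", "tde" if config.kind == "burst" else None)
    if method == "tde":
        return prep.prepare_tde_pipeline(
            ts,
            n_embeddings=int(p.get("n_embeddings", 15)),
            n_components=p.get("n_components"),
        )
    if method == "ae":
        band = p.get("band")
        if band:
            return prep.prepare_ae_pipeline(ts, band[0], band[1])
        return prep.prepare_ae_pipeline(ts)
    raise ConfigError(f"unknown preparation method {method!r}")


@_stage("model")
def _run_model(config: PipelineConfig, pd_: PreparedData):
    m = config.model
    n_runs = int(m.get("n_runs", 1))
    opts = dict(m.get("fit", {}))
    if m["type"] == "hmm":
        factory = lambda: GaussianHMM(pd_, int(m["n_states"]))
    else:
        factory = lambda: DyNeMo(pd_, int(m["n_states"]))
    ensemble = fit_ensemble(factory, n_runs, seed=config.seed, fit_kwargs=opts)
    return ensemble, select_best_run(ensemble)


@_stage("spectra")
def _run_spectra(config: PipelineConfig, ts, pd_, best):
    s = config.spectra
    offsets = [im[0] for im in pd_.index_maps]
    kwargs = {
        k: s[k]
        for k in ("window_length", "n_tapers", "time_half_bandwidth", "overlap")
        if k in s
    }
    if isinstance(best, HMMResults):
        courses = best.state_probabilities()
        se = spec.multitaper_state_spectra(ts, courses, sample_offsets=offsets, **kwargs)
    else:
        courses = best.split_alpha()
        se = spec.glm_mode_spectra(ts, courses, sample_offsets=offsets, **kwargs)
    coh = spec.coherence_from_cpsd(se)
    return se, coh


@_stage("summary")
def _run_summary(config: PipelineConfig, ts, pd_, best) -> dict:
    fs = ts.sampling_frequency
    out = {}
    if isinstance(best, HMMResults):
        paths = best.viterbi()
        K = best.n_states
        for stat in ("fractional_occupancy", "mean_lifetime", "mean_interval",
                     "switching_rate"):
            out[stat] = summ.summary_table(paths, fs, stat, n_states=K).values
        env = prep.amplitude_envelope(ts)
        env_aligned = TimeSeriesSet(
            [a[m] for a, m in zip(env.arrays, pd_.index_maps)], fs
        )
        out["mean_amplitude"] = summ.mean_amplitude(paths, env_aligned, n_states=K)
    else:
        stats = summ.mixing_stats(best.split_alpha(renormalized=True))
        out["mixing_mean"] = stats["mean"]
        out["mixing_sd"] = stats["sd"]
        out["mixing_correlation"] = stats["correlation"]
    return out


@_stage("static")
def _run_static(config: PipelineConfig, ts: TimeSeriesSet) -> dict:
    s = config.spectra
    bands = s.get("bands", [[1, 4], [4, 8], [8, 12], [12, 30]])
    se = spec.static_spectra(ts)
    coh = spec.coherence_from_cpsd(se)
    freqs = se.frequencies
    out = {"spectra": se, "coherence": coh, "bands": bands}
    power, aec_nets, coh_band, masks = [], [], [], []
    frac = float(s.get("edge_fraction", 0.05))
    for lo, hi in bands:
        power.append(spec.power_map(se, band=(lo, hi)))
        aec_nets.append(spec.aec(ts, (lo, hi)))
        sel = (freqs >= lo) & (freqs <= hi)
        cb = np.nanmean(coh[..., sel], axis=-1)
        coh_band.append(cb)
        from .group import threshold_topk

        masks.append(threshold_topk(np.nanmean(cb[:, 0], axis=0), frac))
    out["power_maps"] = np.stack(power)
    out["aec"] = np.stack(aec_nets)
    out["coherence_band"] = np.stack(coh_band)
    out["edge_masks"] = np.stack(masks)
    return out


def run_pipeline(
    config: PipelineConfig | dict,
    ts: TimeSeriesSet,
    output_dir: str | Path | None = None,
) -> dict:
    """Execute a full workflow; returns the artifact dict and writes it
    (plus provenance) to the output directory."""
    if isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    out_dir = Path(output_dir or config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {"config": config}

    try:
        if config.kind == "static":
            artifacts.update(_run_static(config, ts))
        else:
            pd_ = _run_prepare(config, ts)
            artifacts["prepared"] = pd_
            ensemble, best = _run_model(config, pd_)
            artifacts["ensemble"] = ensemble
            artifacts["best"] = best
            if isinstance(best, HMMResults):
                artifacts["dual"] = best.dual_estimate(ts)
            se, coh = _run_spectra(config, ts, pd_, best)
            artifacts["spectra"] = se
            artifacts["coherence"] = coh
            artifacts["summary"] = _run_summary(config, ts, pd_, best)
    finally:
        _write_artifacts(artifacts, out_dir, config)
    return artifacts


def _write_artifacts(artifacts: dict, out_dir: Path, config: PipelineConfig):
    """Persist whatever stages completed; partial results are kept."""
    if "prepared" in artifacts:
        artifacts["prepared"].save_record(out_dir / "preparation.json")
    if "best" in artifacts:
        artifacts["best"].save(out_dir / "model")
    if "spectra" in artifacts:
        artifacts["spectra"].save(out_dir / "spectra")
    if "summary" in artifacts:
        for name, values in artifacts["summary"].items():
            _save_csv(out_dir / f"summary_{name}.csv", values.reshape(values.shape[0], -1))
    if "power_maps" in artifacts:
        np.savez(
            out_dir / "static.npz",
            power_maps=artifacts["power_maps"],
            aec=artifacts["aec"],
            coherence_band=artifacts["coherence_band"],
            edge_masks=artifacts["edge_masks"],
        )
    cfg = config.to_dict()
    provenance = {
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "free_energies": (
            artifacts["ensemble"].free_energies.tolist()
            if "ensemble" in artifacts
            else None
        ),
        "best_run": (
            artifacts["ensemble"].best_index if "ensemble" in artifacts else None
        ),
    }
    try:
        from importlib.metadata import version

        provenance["statedyn_version"] = version("statedyn")
    except Exception:
        provenance["statedyn_version"] = "unknown"
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2))
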