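"""Synthetic inputs with the statistical structure the model assumes.

Every generator is a pure function of its parameters and seed, and its
defaults are the study conditions used throughout the test suite: networks
of n = 20 regions, cohorts of 30 seizures, 30% hidden regions, onset noise
of sigma_t = 5 s.  Network weights are Bernoulli-masked log-normal
magnitudes (heavy-tailed like streamline counts) normalized so the maximal
ingoing sum is 1.  Seizures follow the generative direction of the
hierarchical model exactly: c ~ N(0, 1), t = P_{W,q}(c), observed seizing
onsets perturbed by Gaussian noise; ground truth is always returned
alongside the observation so every scorer is testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .connectome import Connectome
from .constants import DEFAULT_CONSTANTS, ModelConstants
from .dynamics import ExcitationParams, _q_array
from .observations import MultiSeizureData, SeizureObservation
from .seeg import ChannelRecord
from .validation import ResectionScenario

__all__ = [
    "generate_network",
    "generate_seizure",
    "SyntheticCohortSpec",
    "generate_cohort",
    "generate_seeg_signal",
    "generate_resection_scenario",
    "DEFAULT_TRUE_Q",
]

# a moderately coupled excitation function used as the default ground truth:
# isolated regions seize slowly unless excitable, seizing input accelerates
DEFAULT_TRUE_Q = ExcitationParams(q_aa=-4.0, q_ab=0.0, q_ba_star=2.0, q_bb_star=3.0)


def generate_network(
    n: int, density: float = 0.5, seed=None, *, weight_sigma: float = 1.0,
    region_ids=None,
) -> Connectome:
    """Random directed normalized network.

    Off-diagonal edges are present with probability ``density`` and carry
    log-normal(0, weight_sigma) magnitudes; the matrix is normalized by its
    maximal ingoing-weight sum.
    """
    if n < 2:
        raise ValueError("need at least two regions")
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    W = rng.lognormal(0.0, weight_sigma, size=(n, n))
    W *= rng.random((n, n)) < density
    np.fill_diagonal(W, 0.0)
    max_in = W.sum(axis=1).max()
    if max_in <= 0:  # pathological sparse draw; re-seed deterministically
        return generate_network(n, density, rng, weight_sigma=weight_sigma,
                                region_ids=region_ids)
    return Connectome(W / max_in, region_ids)


def generate_seizure(
    W: Connectome,
    q=DEFAULT_TRUE_Q,
    hidden_fraction: float = 0.3,
    noise_sd: float = 5.0,
    seed=None,
    constants: ModelConstants = DEFAULT_CONSTANTS,
):
    """Simulate one seizure and its partial noisy observation.

    Returns ``(obs, truth)`` where ``truth`` is a dict with the drawn
    excitabilities ``c`` and noiseless onset times ``t``.  Hidden regions are
    chosen uniformly at random; observed regions with true onset >= t_lim
    are non-seizing; observed seizing onsets get Gaussian noise clipped to
    (0, t_lim].
    """
    if not 0 <= hidden_fraction < 1:
        raise ValueError("hidden_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = W.n_regions
    c = rng.standard_normal(n)
    t = _kernels.sim_event(W.weights, _q_array(q), c, np.inf)
    n_hidden = int(round(hidden_fraction * n))
    hidden = rng.choice(n, size=n_hidden, replace=False)
    status = np.array(["non-seizing"] * n, dtype=object)
    onset = np.full(n, np.inf)
    t_lim = constants.t_lim
    for i in range(n):
        if t[i] < t_lim:
            status[i] = "seizing"
            onset[i] = np.clip(t[i] + rng.normal(0.0, noise_sd), 1e-3, t_lim)
    status[hidden] = "hidden"
    onset[hidden] = np.inf
    obs = SeizureObservation(list(W.region_ids), status, onset)
    return obs, {"c": c, "t": t}


@dataclass
class SyntheticCohortSpec:
    """Study conditions of a synthetic cohort."""

    n_regions: int = 20
    n_patients: int = 15
    seizures_per_patient: int = 2
    density: float = 0.5
    weight_sigma: float = 1.0
    true_q: ExcitationParams = DEFAULT_TRUE_Q
    hidden_fraction: float = 0.3
    noise_sd: float = 5.0
    seed: int = 0
    constants: ModelConstants = field(default_factory=ModelConstants)

    @property
    def n_seizures(self) -> int:
        return self.n_patients * self.seizures_per_patient


def generate_cohort(spec: SyntheticCohortSpec):
    """Generate a multi-seizure cohort: one network per patient, at most two
    seizures per patient (mirroring the training-set design), shared true q.

    Returns ``(data, truths)`` with ``truths`` a list of per-seizure ground
    truth dicts aligned with ``data.seizures``.
    """
    root = np.random.SeedSequence(spec.seed)
    patient_seeds = root.spawn(spec.n_patients)
    seizures = []
    truths = []
    for p, ps in enumerate(patient_seeds):
        net_seed, *sz_seeds = ps.spawn(1 + spec.seizures_per_patient)
        W = generate_network(
            spec.n_regions, spec.density, net_seed, weight_sigma=spec.weight_sigma
        )
        for ss in sz_seeds:
            obs, truth = generate_seizure(
                W, spec.true_q, spec.hidden_fraction, spec.noise_sd, ss, spec.constants
            )
            truth["patient"] = p
            seizures.append((obs, W))
            truths.append(truth)
    return MultiSeizureData(seizures), truths


def save_cohort(data: MultiSeizureData, truths, out_dir) -> None:
    """Serialize a cohort: per-seizure connectome CSV, observation CSV,
    ground-truth CSV, and a manifest JSON listing the files."""
    import json
    from pathlib import Path

    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for k, ((obs, W), truth) in enumerate(zip(data, truths)):
        names = {
            "connectome": f"seizure_{k:03d}_connectome.csv",
            "observation": f"seizure_{k:03d}_observation.csv",
            "ground_truth": f"seizure_{k:03d}_truth.csv",
        }
        W.to_csv(out / names["connectome"])
        obs.to_csv(out / names["observation"])
        pd.DataFrame(
            {"region_id": W.region_ids, "c_true": truth["c"], "t_true": truth["t"]}
        ).to_csv(out / names["ground_truth"], index=False)
        manifest.append({"seizure": k, "patient": truth.get("patient"), **names})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def generate_seeg_signal(
    region_onsets: dict[str, float],
    fs: float = 512.0,
    duration: float | None = None,
    *,
    band: tuple[float, float] = (4.0, 30.0),
    gain: float = 10.0,
    seizure_end: float | None = None,
    clinical_onset: float | None = None,
    seed=None,
) -> list[ChannelRecord]:
    """Band-limited-noise channels whose power rises ``gain``-fold at onset.

    One channel per region; ``region_onsets`` maps channel/region ids to
    onset times in recording seconds (np.inf = never seizes).  The signal is
    filtered white noise whose amplitude is multiplied by sqrt(gain) from
    the region's onset until ``seizure_end`` (default: end of recording) —
    i.e. a gain-fold power step, detectable when gain exceeds the detection
    threshold delta.  The clinician mark defaults to the earliest onset;
    the recording must cover a 60 s baseline before it.
    """
    from scipy.signal import butter, lfilter

    rng = np.random.default_rng(seed)
    finite = [t for t in region_onsets.values() if np.isfinite(t)]
    if clinical_onset is None:
        if not finite:
            raise ValueError("need a finite onset or an explicit clinical_onset")
        clinical_onset = min(finite)
    if clinical_onset < 60.0:
        raise ValueError("recording must cover a 60 s baseline before the mark")
    if duration is None:
        duration = (max(finite) if finite else clinical_onset) + 90.0
    n_samp = int(round(duration * fs))
    b, a = butter(4, [band[0] / (fs / 2), band[1] / (fs / 2)], btype="band")
    t_axis = np.arange(n_samp) / fs
    end = duration if seizure_end is None else seizure_end
    records = []
    for cid, onset in region_onsets.items():
        x = lfilter(b, a, rng.standard_normal(n_samp))
        if np.isfinite(onset):
            burst = (t_axis >= onset) & (t_axis < end)
            x[burst] *= np.sqrt(gain)
        records.append(
            ChannelRecord(str(cid), x, fs, clinical_onset, midpoint=np.zeros(3))
        )
    return records


def generate_resection_scenario(
    W: Connectome,
    q,
    c_true: np.ndarray,
    strategy: str = "resect_true_ez",
    *,
    k: int = 0,
    c_h: float = 2.0,
    seed=None,
    engel: str | None = None,
) -> ResectionScenario:
    """Build a resection set for virtual-surgery experiments.

    ``resect_true_ez`` removes every region whose true excitability exceeds
    c_h (the ground-truth epileptogenic zone); ``resect_random_k`` removes k
    regions uniformly at random.
    """
    rng = np.random.default_rng(seed)
    c_true = np.asarray(c_true, dtype=float)
    if strategy == "resect_true_ez":
        resected = {r for r, c in zip(W.region_ids, c_true) if c > c_h}
    elif strategy == "resect_random_k":
        if not 0 <= k <= W.n_regions:
            raise ValueError("k out of range")
        resected = set(
            np.asarray(W.region_ids, dtype=object)[
                rng.choice(W.n_regions, size=k, replace=False)
            ]
        ) if k else set()
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return ResectionScenario(resected, engel)
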