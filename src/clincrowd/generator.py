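"""Agent-based synthetic generator for the three-round clinician experiment.

Emulates the statistical structure the analysis assumes: heterogeneous
initial accuracy, DeGroot-style revision toward the displayed neighbor mean
with accuracy-dependent self-weight (accurate clinicians revise less),
independent partial shrinkage toward truth in the control arm, and
risk-threshold-driven treatment recommendations.

Default study shape mirrors the experiment: 7 vignettes x (8 network + 4
control) trials = 84 trials, 40 clinicians per trial, 3 rounds, one fixed
40-node degree-4 topology shared by all networked trials.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from . import core
from .core import (
    CONTROL,
    NETWORK,
    ClinicianRoundResponse,
    NetworkTopology,
    TrialConfig,
    TrialRecord,
)
from .errors import InvalidParametersError


@dataclass(frozen=True)
class ClinicianSkillProfile:
    """Latent skill of one simulated clinician.

    bias
        systematic offset from truth, percentage points (signed).
    noise_sd
        sd of round-level estimate noise, percentage points.
    stubbornness_base
        baseline self-weight in the revision rule, in [0, 1].
    """

    bias: float
    noise_sd: float
    stubbornness_base: float

    def __post_init__(self):
        if self.noise_sd < 0:
            raise InvalidParametersError("noise_sd must be >= 0")
        if not 0.0 <= self.stubbornness_base <= 1.0:
            raise InvalidParametersError("stubbornness_base must lie in [0, 1]")


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    truth
        correct risk estimate for the vignette, in [0, 100].
    bias_spread
        sd of the normal clinician-bias distribution (pp).  35 gives, after
        clipping to [0, 100] across the default vignettes, a mean absolute
        initial error near 23 pp and an initial-accuracy quartile spread
        from the high 90s down to roughly 50, the heterogeneity the
        quartile analyses need.
    noise_sd
        sd of round-level estimate noise (pp).
    stubbornness_base
        baseline self-weight shared by all clinicians.
    alpha_link
        strength of the accuracy -> self-weight coupling; 0 switches the
        revision-accuracy correlation off.
    control_gain
        per-round fractional shrinkage toward truth under independent
        reflection; 0.06 over two revision rounds moves mean error down by
        roughly 2-3 pp.
    control_noise_sd
        sd of the control-arm revision noise (pp).
    thresholds
        strictly increasing cut-points on [0, 100] mapping an estimate to a
        recommendation; len(thresholds) == len(options) - 1.
    seed
        RNG seed used when no generator is passed explicitly.
    """

    truth: float = 50.0
    bias_spread: float = 35.0
    noise_sd: float = 5.0
    stubbornness_base: float = 0.3
    alpha_link: float = 0.6
    control_gain: float = 0.06
    control_noise_sd: float = 3.0
    thresholds: tuple = (35.0, 65.0)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.control_gain <= 1.0:
            raise InvalidParametersError("control_gain must lie in [0, 1]")
        if list(self.thresholds) != sorted(set(self.thresholds)):
            raise InvalidParametersError("thresholds must be strictly increasing")


def _clip(x):
    return np.clip(x, 0.0, 100.0)


def sample_initial_estimates(config: GeneratorConfig, n: int, rng: np.random.Generator):
    """Draw skill profiles and round-1 estimates for ``n`` clinicians.

    estimate_i = clip(truth + bias_i + noise_i, 0, 100) with
    bias_i ~ N(0, bias_spread) and noise_i ~ N(0, noise_sd).
    """
    if n < 1:
        raise InvalidParametersError("need at least one clinician")
    biases = rng.normal(0.0, config.bias_spread, n) if config.bias_spread > 0 else np.zeros(n)
    noise = rng.normal(0.0, config.noise_sd, n) if config.noise_sd > 0 else np.zeros(n)
    estimates = _clip(config.truth + biases + noise)
    profiles = [
        ClinicianSkillProfile(
            bias=float(b),
            noise_sd=config.noise_sd,
            stubbornness_base=config.stubbornness_base,
        )
        for b in biases
    ]
    return profiles, estimates


def stubbornness(
    profile: ClinicianSkillProfile, initial_error: float, config: GeneratorConfig
) -> float:
    """Self-weight w in [0,1]; non-increasing in initial error when alpha_link > 0.

    w = clip(base + alpha_link * (1 - error/100), 0, 1): a perfectly accurate
    clinician keeps weight base + alpha_link on their own estimate, a
    maximally wrong one keeps only base.
    """
    if not 0.0 <= initial_error <= 100.0:
        raise InvalidParametersError("initial_error must lie in [0, 100]")
    w = profile.stubbornness_base + config.alpha_link * (1.0 - initial_error / 100.0)
    return float(np.clip(w, 0.0, 1.0))


def network_revision(current: float, peer_mean: float, w: float) -> float:
    """Convex self/peer combination: w*current + (1-w)*peer_mean, clipped."""
    return float(_clip(w * current + (1.0 - w) * peer_mean))


def control_revision(
    current: float, truth: float, config: GeneratorConfig, rng: np.random.Generator
) -> float:
    """Independent reflection: partial shrinkage toward truth plus noise."""
    noise = rng.normal(0.0, config.control_noise_sd) if config.control_noise_sd > 0 else 0.0
    return float(_clip(current + config.control_gain * (truth - current) + noise))


def map_recommendation(estimate: float, thresholds: Sequence[float], options: Sequence[str]) -> str:
    """Map a risk estimate to a recommendation by threshold band.

    An estimate exactly at a cut-point maps to the higher-index option.
    """
    thresholds = list(thresholds)
    if thresholds != sorted(set(thresholds)):
        raise InvalidParametersError("thresholds must be strictly increasing")
    if len(thresholds) != len(options) - 1:
        raise InvalidParametersError(
            f"{len(thresholds)} thresholds require {len(thresholds) + 1} options, "
            f"got {len(options)}"
        )
    return options[bisect.bisect_right(thresholds, estimate)]


def _clinician_id(i: int, n: int) -> str:
    width = max(2, len(str(n - 1)))
    return f"c{i:0{width}d}"


def simulate_trial(
    trial_config: TrialConfig,
    gen_config: GeneratorConfig,
    topology: Optional[NetworkTopology] = None,
    rng: Optional[np.random.Generator] = None,
) -> TrialRecord:
    """Simulate one complete trial panel.

    Networked clinicians revise in round r toward the mean of their
    neighbors' round r-1 estimates, with an accuracy-dependent self-weight
    fixed by their round-1 error.  Control clinicians shrink independently
    toward truth.  Recommendations are recomputed from each round's estimate.
    """
    cond = trial_config.condition
    if cond == NETWORK and topology is None:
        raise InvalidParametersError("network trial requires a topology")
    if cond == CONTROL and topology is not None:
        raise InvalidParametersError("control trial must not carry a topology")
    if topology is not None and topology.n_nodes != trial_config.n_clinicians:
        raise InvalidParametersError("topology size != panel size")

    if rng is None:
        rng = np.random.default_rng(gen_config.seed)
    n = trial_config.n_clinicians
    cfg = replace(gen_config, truth=trial_config.truth)

    profiles, est = sample_initial_estimates(cfg, n, rng)
    initial_error = np.abs(est - cfg.truth)
    weights = np.array(
        [stubbornness(p, e, cfg) for p, e in zip(profiles, initial_error)]
    )
    # random node placement; unobservable for synthetic ids but kept explicit
    nodes = rng.permutation(n) if cond == NETWORK else None

    ids = [_clinician_id(i, n) for i in range(n)]
    responses = []
    estimates_by_round = {1: est}
    for r in range(2, trial_config.n_rounds + 1):
        prev = estimates_by_round[r - 1]
        if cond == NETWORK:
            node_est = {int(nodes[i]): prev[i] for i in range(n)}
            new = np.array(
                [
                    network_revision(
                        prev[i],
                        core.peer_signal(topology, node_est, int(nodes[i])),
                        weights[i],
                    )
                    for i in range(n)
                ]
            )
        else:
            new = np.array(
                [control_revision(prev[i], cfg.truth, cfg, rng) for i in range(n)]
            )
        estimates_by_round[r] = new

    for r in range(1, trial_config.n_rounds + 1):
        for i in range(n):
            responses.append(
                ClinicianRoundResponse(
                    clinician_id=ids[i],
                    round=r,
                    estimate=float(estimates_by_round[r][i]),
                    recommendation=map_recommendation(
                        estimates_by_round[r][i], cfg.thresholds, trial_config.options
                    ),
                )
            )

    return TrialRecord(
        trial_id="trial",
        config=trial_config,
        responses=responses,
        topology=topology if cond == NETWORK else None,
        node_of={ids[i]: int(nodes[i]) for i in range(n)} if cond == NETWORK else None,
    )


def trial_seed_sequence(master_seed: int, trial_index: int) -> np.random.SeedSequence:
    """Per-trial RNG stream: child ``(trial_index,)`` of the master seed.

    Streams depend only on (master_seed, trial_index), so appending trials
    never perturbs earlier ones.
    """
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(trial_index,))


def simulate_study(
    vignettes,
    gen_config: GeneratorConfig,
    n_network: int = 8,
    n_control: int = 4,
    master_seed: int = 0,
    degree: int = 4,
    n_clinicians: int = 40,
    n_rounds: int = 3,
):
    """Simulate a full multi-vignette study; returns a list of TrialRecords.

    ``vignettes`` is a sequence of objects with attributes
    ``id, truth, options, correct_option, thresholds``.  Default shape is
    7 x (8 network + 4 control) = 84 trials.  All networked trials share one
    topology: the canonical 40/4 graph at the default size, otherwise a
    study-specific seeded draw.
    """
    if n_network < 0 or n_control < 0 or n_network + n_control == 0:
        raise InvalidParametersError("need at least one trial per vignette")

    if n_clinicians == 40 and degree == 4:
        topo = core.canonical_topology()
    else:
        topo = core.generate_regular_random_network(
            n_clinicians, degree, seed=core.CANONICAL_TOPOLOGY_SEED
        )

    trials = []
    index = 0
    for v in vignettes:
        base = TrialConfig(
            vignette_id=v.id,
            condition=NETWORK,
            truth=v.truth,
            options=tuple(v.options),
            correct_option=v.correct_option,
            n_clinicians=n_clinicians,
            n_rounds=n_rounds,
        )
        gcfg = replace(gen_config, truth=v.truth, thresholds=tuple(v.thresholds))
        for cond, count in ((NETWORK, n_network), (CONTROL, n_control)):
            for j in range(count):
                rng = np.random.default_rng(trial_seed_sequence(master_seed, index))
                cfg = replace(base, condition=cond)
                rec = simulate_trial(
                    cfg,
                    gcfg,
                    topology=topo if cond == NETWORK else None,
                    rng=rng,
                )
                tag = "net" if cond == NETWORK else "ctl"
                rec.trial_id = f"{v.id}-{tag}-{j:02d}"
                trials.append(rec)
                index += 1
    return trials
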