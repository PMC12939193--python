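"""Synthetic two-group cohorts with planted Markov-switching phase-locking states.

The generator emulates the structure of a parcellated resting-state fMRI
study: every scan is a T x N matrix of band-limited signals (TR = 2 s,
N = 90 regions by default) in which a hidden Markov chain switches between
S planted spatial phase configurations.  While state ``s`` is active,
regions inside that state's community oscillate in phase with a shared
low-frequency carrier and all remaining regions are offset by a fixed
phase separation (pi/2 by default, placing them at the ``cos = 0``
boundary of the phase-coherence measure).  White Gaussian noise is added
on top.

Two groups differ only through their transition models, so a planted
difference in state occupancy of configurable size is available as ground
truth for power and calibration studies.  The construction is an
engineering stand-in for the metastable switching regime observed in real
resting-state recordings: it makes true per-volume state labels exact and
the expected leading-eigenvector structure known in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .exceptions import ConfigurationError
from .phase import ParcelTimeSeries
from ._seeds import derive_seed

__all__ = [
    "StateTemplate",
    "TransitionModel",
    "CohortConfig",
    "generate_state_templates",
    "sticky_transition_model",
    "occupancy_shift_models",
    "simulate_subject",
    "generate_cohort",
]

#: Fraction of a template's squared norm carried by its (positive) community.
#: Kept small so each template points along the dominant eigen-direction of
#: its own planted coherence pattern (the complement block), with the
#: community entries providing the sign structure that identifies the state.
COMMUNITY_WEIGHT = 0.01


@dataclass(frozen=True)
class StateTemplate:
    """A planted phase-locking state.

    ``values`` is a unit-norm N-vector; the *community* (the set of regions
    oscillating in phase while the state is active) is exactly the set of
    indices with positive values.
    """

    values: np.ndarray
    community: frozenset[int]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if abs(np.linalg.norm(v) - 1.0) > 1e-12:
            raise ConfigurationError("template values must have unit norm")
        if self.community != frozenset(np.flatnonzero(v > 0).tolist()):
            raise ConfigurationError("community must equal {n: values[n] > 0}")


@dataclass(frozen=True)
class TransitionModel:
    """Row-stochastic transition matrix P plus initial distribution pi0."""

    P: np.ndarray
    pi0: np.ndarray

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        pi0 = np.asarray(self.pi0, dtype=float)
        object.__setattr__(self, "P", P)
        object.__setattr__(self, "pi0", pi0)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ConfigurationError("P must be square")
        if (P < 0).any() or (pi0 < 0).any():
            raise ConfigurationError("probabilities must be non-negative")
        if np.abs(P.sum(axis=1) - 1.0).max() > 1e-12:
            raise ConfigurationError("rows of P must sum to 1")
        if abs(pi0.sum() - 1.0) > 1e-12:
            raise ConfigurationError("pi0 must sum to 1")
        if pi0.shape != (P.shape[0],):
            raise ConfigurationError("pi0 length must match P")

    @property
    def n_states(self) -> int:
        return self.P.shape[0]

    def stationary_distribution(self) -> np.ndarray:
        """Stationary distribution via the left-eigenvector of P."""
        eigvals, eigvecs = np.linalg.eig(self.P.T)
        idx = int(np.argmin(np.abs(eigvals - 1.0)))
        pi = np.real(eigvecs[:, idx])
        pi = np.abs(pi)
        return pi / pi.sum()


@dataclass
class CohortConfig:
    """Study-level configuration of a synthetic two-group cohort.

    Defaults mirror the acquisition regime the generator emulates: N = 90
    regions, T = 200 volumes (valid range 180-240 in the emulated
    protocol), TR = 2 s, carriers inside the 0.01-0.08 Hz analysis band.
    """

    n_regions: int = 90
    n_volumes: int = 200
    tr: float = 2.0
    n_states: int = 4
    n_per_group: tuple[int, int] = (20, 20)
    carrier_band: tuple[float, float] = (0.02, 0.06)
    phase_separation: float = np.pi / 2
    noise_sd: float = 0.2
    group_transition_models: tuple[TransitionModel, TransitionModel] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_volumes < 2 or self.n_regions < 2:
            raise ConfigurationError("need T >= 2 and N >= 2")
        lo, hi = self.carrier_band
        if not (0.01 <= lo < hi <= 0.08):
            raise ConfigurationError("carrier_band must lie inside (0.01, 0.08) Hz")
        if not (0.0 < self.phase_separation <= np.pi):
            raise ConfigurationError("phase_separation must be in (0, pi]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if any(n < 1 for n in self.n_per_group):
            raise ConfigurationError("both groups need at least one scan")
        if self.group_transition_models is None:
            tm = sticky_transition_model(self.n_states)
            self.group_transition_models = (tm, tm)
        for tm in self.group_transition_models:
            if tm.n_states != self.n_states:
                raise ConfigurationError(
                    "transition models must have n_states states"
                )


def generate_state_templates(S: int, N: int, seed: int) -> list[StateTemplate]:
    """Generate S planted state templates over N regions.

    Regions are partitioned into S disjoint communities of roughly N/S
    regions.  Template ``s`` is positive on its community and negative
    elsewhere, with a small seeded jitter on the magnitudes, normalized to
    unit Euclidean norm.  The community carries ``COMMUNITY_WEIGHT`` of the
    squared norm, so each template is nearly (anti-)parallel to the
    indicator of its community's complement — the leading eigen-direction
    produced by the planted phase pattern.
    """
    if S < 2 or S > N:
        raise ConfigurationError(f"need 2 <= S <= N, got S={S}, N={N}")
    rng = np.random.default_rng(seed)
    sizes = np.full(S, N // S)
    sizes[: N % S] += 1
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    templates: list[StateTemplate] = []
    for s in range(S):
        community = np.arange(bounds[s], bounds[s + 1])
        m = community.size
        v = np.empty(N)
        jitter = rng.uniform(0.9, 1.1, size=N)
        v.fill(-np.sqrt((1.0 - COMMUNITY_WEIGHT) / (N - m)))
        v[community] = np.sqrt(COMMUNITY_WEIGHT / m)
        v *= jitter
        v /= np.linalg.norm(v)
        templates.append(
            StateTemplate(values=v, community=frozenset(community.tolist()))
        )
    return templates


def sticky_transition_model(
    S: int, stay: float = 0.6, stationary: np.ndarray | None = None
) -> TransitionModel:
    """Markov model ``P = stay * I + (1 - stay) * 1 pi^T``.

    This family has stationary distribution exactly ``pi`` (uniform by
    default) with a stickiness parameter controlling dwell times: state s
    is left with probability ``(1 - stay) * (1 - pi_s)`` per volume.  The
    default ``stay = 0.6`` with uniform pi over 4 states gives mean dwell
    times around 3.3 volumes (~7 s at TR = 2 s), in the range reported for
    empirical phase-locking states.
    """
    if not (0.0 <= stay < 1.0):
        raise ConfigurationError("stay must be in [0, 1)")
    pi = (
        np.full(S, 1.0 / S)
        if stationary is None
        else np.asarray(stationary, dtype=float)
    )
    if pi.shape != (S,) or (pi < 0).any() or abs(pi.sum() - 1.0) > 1e-12:
        raise ConfigurationError("stationary must be a length-S distribution")
    P = stay * np.eye(S) + (1.0 - stay) * np.outer(np.ones(S), pi)
    # guard against float round-off in the row sums
    P /= P.sum(axis=1, keepdims=True)
    return TransitionModel(P=P, pi0=pi.copy())


def occupancy_shift_models(
    S: int, shifted_state: int, gap: float, stay: float = 0.6
) -> tuple[TransitionModel, TransitionModel]:
    """Pair of transition models whose stationary occupancies differ by
    ``gap`` in one designated state.

    Group A is uniform; group B's stationary probability of
    ``shifted_state`` (1-based) is raised by ``gap`` (negative values lower
    it), with the remaining states rescaled to keep a distribution.
    """
    if not 1 <= shifted_state <= S:
        raise ConfigurationError("shifted_state must be in 1..S")
    base = np.full(S, 1.0 / S)
    target = base.copy()
    j = shifted_state - 1
    if not -base[j] < gap < 1.0 - base[j]:
        raise ConfigurationError("gap pushes the occupancy outside (0, 1)")
    target[j] += gap
    others = np.arange(S) != j
    target[others] *= (1.0 - target[j]) / target[others].sum()
    return (
        sticky_transition_model(S, stay=stay),
        sticky_transition_model(S, stay=stay, stationary=target),
    )


def _sample_chain(
    tm: TransitionModel, T: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample T steps of the hidden state chain; labels are 1-based."""
    S = tm.n_states
    states = np.empty(T, dtype=int)
    states[0] = rng.choice(S, p=tm.pi0)
    cumP = np.cumsum(tm.P, axis=1)
    u = rng.random(T - 1)
    for t in range(1, T):
        states[t] = np.searchsorted(cumP[states[t - 1]], u[t - 1])
    return states + 1


def simulate_subject(
    config: CohortConfig,
    transitions: TransitionModel,
    templates: list[StateTemplate],
    seed: int,
) -> tuple[ParcelTimeSeries, np.ndarray]:
    """Simulate one scan and its ground-truth per-volume state labels.

    Region ``n`` at volume ``t`` (active state ``s_t``) takes the value
    ``cos(2 pi f t TR + phi_n(s_t)) + eps`` where ``f`` is a per-subject
    carrier drawn uniformly from ``carrier_band``, ``phi_n(s) = 0`` for
    regions in state s's community and ``phase_separation`` otherwise, and
    ``eps ~ Normal(0, noise_sd^2)``.  Labels are the sampled Markov chain
    (1-based).
    """
    if not templates:
        raise ConfigurationError("templates must be non-empty")
    if len(templates) != transitions.n_states:
        raise ConfigurationError(
            f"{len(templates)} templates for a {transitions.n_states}-state chain"
        )
    rng = np.random.default_rng(seed)
    f = rng.uniform(*config.carrier_band)
    labels = _sample_chain(transitions, config.n_volumes, rng)
    t_grid = np.arange(config.n_volumes) * config.tr
    # phase offset matrix: offsets[s, n] = 0 inside community s, else sep
    offsets = np.full((len(templates), config.n_regions), config.phase_separation)
    for s, tpl in enumerate(templates):
        offsets[s, list(tpl.community)] = 0.0
    phase = 2.0 * np.pi * f * t_grid[:, None] + offsets[labels - 1]
    data = np.cos(phase)
    if config.noise_sd > 0:
        data = data + rng.normal(0.0, config.noise_sd, size=data.shape)
    ts = ParcelTimeSeries(data=data, tr=config.tr)
    return ts, labels


def simulate_cohort(
    config: CohortConfig,
) -> tuple[list[ParcelTimeSeries], list[str], list[np.ndarray], list[StateTemplate]]:
    """In-memory cohort: scans, group labels, true label sequences, templates.

    Scan seeds are derived deterministically from ``config.seed`` so the
    cohort is bit-reproducible.
    """
    templates = generate_state_templates(
        config.n_states, config.n_regions, derive_seed(config.seed, "templates")
    )
    scans: list[ParcelTimeSeries] = []
    groups: list[str] = []
    truths: list[np.ndarray] = []
    for g, (name, n_scans) in enumerate(zip("AB", config.n_per_group)):
        tm = config.group_transition_models[g]
        for i in range(n_scans):
            scan_id = f"{name}{i + 1:03d}"
            ts, labels = simulate_subject(
                config, tm, templates, derive_seed(config.seed, "scan", name, i)
            )
            ts.scan_id = scan_id
            scans.append(ts)
            groups.append(name)
            truths.append(labels)
    return scans, groups, truths, templates


def generate_cohort(config: CohortConfig, out_dir: str | Path) -> Path:
    """Write a full synthetic cohort to ``out_dir``.

    Layout::

        out_dir/
          manifest.tsv              scan_id, group, path (relative)
          cohort_config.yaml        the generating parameters
          scans/<scan_id>.tsv       T x N matrix, header = region labels
          ground_truth/templates.tsv
          ground_truth/<scan_id>_labels.txt

    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    scans_dir = out_dir / "scans"
    truth_dir = out_dir / "ground_truth"
    scans_dir.mkdir(parents=True, exist_ok=True)
    truth_dir.mkdir(parents=True, exist_ok=True)

    scans, groups, truths, templates = simulate_cohort(config)
    rows = []
    for ts, group, labels in zip(scans, groups, truths):
        rel = f"scans/{ts.scan_id}.tsv"
        header = "\t".join(ts.region_labels)
        np.savetxt(
            scans_dir / f"{ts.scan_id}.tsv",
            ts.data,
            delimiter="\t",
            header=header,
            comments="",
            fmt="%.6f",
        )
        np.savetxt(
            truth_dir / f"{ts.scan_id}_labels.txt", labels, fmt="%d"
        )
        rows.append(f"{ts.scan_id}\t{group}\t{rel}")

    template_matrix = np.vstack([tpl.values for tpl in templates])
    np.savetxt(
        truth_dir / "templates.tsv",
        template_matrix,
        delimiter="\t",
        header="\t".join(f"state_{s + 1}" for s in range(len(templates))),
        comments="# rows = states, columns = regions\n",
        fmt="%.8f",
    )
    manifest = out_dir / "manifest.tsv"
    manifest.write_text("scan_id\tgroup\tpath\n" + "\n".join(rows) + "\n")

    cfg = {
        "n_regions": config.n_regions,
        "n_volumes": config.n_volumes,
        "tr": config.tr,
        "n_states": config.n_states,
        "n_group_a": config.n_per_group[0],
        "n_group_b": config.n_per_group[1],
        "carrier_low": config.carrier_band[0],
        "carrier_high": config.carrier_band[1],
        "phase_separation": float(config.phase_separation),
        "noise_sd": config.noise_sd,
        "seed": config.seed,
    }
    (out_dir / "cohort_config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=False))
    return manifest
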