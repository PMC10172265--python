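"""Synthetic moment–RoM cycle sequences with spine-like creep structure.

The generator emulates the statistical signatures of cadaveric lumbar-segment
(L4L5) testing under pure moment loading, so the fitting, statistics and
surrogate stages can be exercised without experimental data:

* saturating creep growth of the loop envelope ``B − A`` over a 30-minute
  block (~20 cycles in flexion–extension FE and lateral bending LB, ~60 in
  axial rotation AR), anchored so the multiplier is exactly 1 at cycle 3;
* stronger creep at body temperature (BT) than room temperature (RT);
* partial recovery of the accumulated growth during 15-minute breaks;
* creep strength decaying over the six blocks of a session (r_load → 1);
* sagittal-symmetry flipping augmentation for LB and AR.

Creep acts multiplicatively on the envelope about its midpoint: at cycle k of
block s the envelope factor is ``Q_s · (1 + c_s (1 − exp(−κ (k − 3))))`` with
per-block gain ``c_s = c0 · d_s`` and cumulative state ``Q_s`` carrying the
unrecovered growth of earlier blocks.  The block decay ``d_s`` defaults to an
exponential approach to a floor, ``d_s = f + (1 − f) e^{−λ(s−1)}``; the
simpler linear law ``d_s = max(0, 1 − δ(s−1))`` is available via config.

The shipped per-temperature calibration (gain, decay, recovery) was tuned
once, against large simulations, to reproduce the reference group medians of
the cadaver study (r_load BT 0.9351 / RT 0.9492, r_break BT 1.0275 /
RT 1.0209, sixth-block pooled r_load 0.9471, first-block FE RoM increase
8.74 % at BT) and is not meant to be adjusted per run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .creep import kendall_tau
from .hysteresis import HysteresisParams, MomentRomLoop, fit_hysteresis, sample_loop
from .sequences import DIRECTIONS, TEMPERATURES, CycleSequence, DatasetSplit

__all__ = [
    "GeneratorConfig",
    "SpecimenProfile",
    "creep_multiplier",
    "decay_factor",
    "generate_specimen",
    "generate_group",
    "apply_break_recovery",
    "flip_params",
    "flip_sequence",
    "build_dataset",
    "assign_tau_t",
    "sequence_ratios",
    "random_loop_params",
]

#: Cycles completed in one 30-minute block, by loading direction.
CYCLES_PER_DIRECTION = {"FE": 20, "LB": 20, "AR": 60}

#: Start hour of block s (1-based) per direction, following the session
#: layout FE → AR (+1 h) → LB (+2 h), repeated every 3 h.
DIRECTION_OFFSET_H = {"FE": 0.0, "AR": 1.0, "LB": 2.0}


def start_hour(direction: str, sequence_index: int) -> float:
    """Total testing time (hours) at which a block starts."""
    return 3.0 * (sequence_index - 1) + DIRECTION_OFFSET_H[direction]


def _symmetric_base(amplitude: float) -> HysteresisParams:
    """Sagittally symmetric base loop: A = −B, branch centers offset ±0.5 Nm."""
    return HysteresisParams(
        A=-amplitude, B=amplitude,
        a1_u=1.3, m1_u=-1.5, a2_u=1.1, m2_u=0.5,
        a1_l=1.3, m1_l=-0.5, a2_l=1.1, m2_l=1.5,
    )


#: Base loop amplitudes (degrees) per direction; AR is the stiffest plane.
BASE_PARAMS = {
    "FE": _symmetric_base(6.5),
    "LB": _symmetric_base(5.0),
    "AR": _symmetric_base(2.5),
}

#: Per-temperature calibration: creep gain c0, decay floor f, decay rate λ,
#: break recovery fraction ρ.  Tuned once (see module docstring).
DEFAULT_CALIBRATION = {
    "BT": {"creep_gain": 0.08573, "decay_floor": 0.610, "decay_rate": 0.310, "recovery_fraction": 0.412},
    "RT": {"creep_gain": 0.05655, "decay_floor": 0.868, "decay_rate": 0.300, "recovery_fraction": 0.403},
}


@dataclass
class GeneratorConfig:
    """Study conditions and noise model of the synthetic generator."""

    temperature_group: str = "BT"
    directions: tuple[str, ...] = ("FE", "LB", "AR")
    n_specimens: int = 3
    sequences_per_direction: int = 6
    cycles_per_sequence: dict = field(default_factory=lambda: dict(CYCLES_PER_DIRECTION))
    base_params: dict = field(default_factory=lambda: dict(BASE_PARAMS))
    # creep law
    creep_gain: float = DEFAULT_CALIBRATION["BT"]["creep_gain"]
    creep_rate: float = 0.4  # κ, 1/cycle
    decay_mode: str = "exp_floor"  # or "linear"
    sequence_decay: float = 0.08  # δ of the linear law
    decay_floor: float = DEFAULT_CALIBRATION["BT"]["decay_floor"]
    decay_rate: float = DEFAULT_CALIBRATION["BT"]["decay_rate"]
    recovery_fraction: float = DEFAULT_CALIBRATION["BT"]["recovery_fraction"]
    # random effects and noise
    specimen_amp_sigma: float = 0.10      # lognormal σ on the loop amplitude
    specimen_shape_sigma: float = 0.05    # lognormal σ on slopes
    specimen_center_sigma: float = 0.10   # normal σ on centers, Nm
    creep_jitter_sigma: float = 0.07      # lognormal σ on the per-block creep gain
    sequence_shape_sigma: float = 0.02    # lognormal σ on slopes, per block
    cycle_shape_sigma: float = 0.0005      # lognormal σ on slopes, per cycle
    cycle_center_sigma: float = 0.002     # normal σ on centers per cycle, Nm
    cycle_rom_sigma: float = 0.01         # normal σ on A, B per cycle, degrees
    noise_sigma: float = 0.05             # observation noise on sampled loops, degrees
    emit: str = "params"                  # "params" (closed form) or "fit" (refit noisy loops)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature_group not in TEMPERATURES:
            raise ValueError(f"temperature_group must be in {TEMPERATURES}")
        for d in self.directions:
            if d not in DIRECTIONS:
                raise ValueError(f"unknown direction {d!r}")
        if min(self.n_specimens, self.sequences_per_direction) < 1:
            raise ValueError("counts must be ≥ 1")
        if not 0.0 <= self.recovery_fraction <= 1.0:
            raise ValueError("recovery_fraction must lie in [0, 1]")
        if self.creep_rate <= 0:
            raise ValueError("creep_rate must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be ≥ 0")
        if self.emit not in ("params", "fit"):
            raise ValueError("emit must be 'params' or 'fit'")
        if self.decay_mode not in ("exp_floor", "linear"):
            raise ValueError("decay_mode must be 'exp_floor' or 'linear'")

    @classmethod
    def for_temperature(cls, temperature: str, **overrides) -> "GeneratorConfig":
        """Config with the shipped calibration of one temperature group."""
        cal = DEFAULT_CALIBRATION[temperature]
        kw = dict(temperature_group=temperature, **cal)
        kw.update(overrides)
        return cls(**kw)


@dataclass(frozen=True)
class SpecimenProfile:
    """Specimen-level random effects: per-direction base loops and creep gain."""

    specimen_id: str
    temperature: str
    base_params: dict
    creep_gain_factor: float


def _saturating(k, c_s: float, kappa: float):
    k = np.asarray(k, dtype=float)
    if np.any(k < 1):
        raise ValueError("cycle index must be ≥ 1")
    return 1.0 + c_s * (1.0 - np.exp(-kappa * (k - 3.0)))


def decay_factor(s: int, config: GeneratorConfig) -> float:
    """Block-level creep decay d_s (d_1 = 1, nonincreasing)."""
    if s < 1:
        raise ValueError("sequence index must be ≥ 1")
    if config.decay_mode == "linear":
        return max(0.0, 1.0 - config.sequence_decay * (s - 1))
    f, lam = config.decay_floor, config.decay_rate
    return f + (1.0 - f) * float(np.exp(-lam * (s - 1)))


def creep_multiplier(k, s: int, c0: float, kappa: float, delta: float):
    """Envelope creep multiplier with the linear block-decay law.

    ``1 + c_s (1 − e^{−κ(k−3)})`` with ``c_s = c0 · max(0, 1 − δ(s−1))``;
    equals 1 at the anchor cycle k = 3 and is nondecreasing in k.
    """
    if s < 1:
        raise ValueError("sequence index must be ≥ 1")
    c_s = c0 * max(0.0, 1.0 - delta * (s - 1))
    return _saturating(k, c_s, kappa)


def apply_break_recovery(envelope_factor_end: float, envelope_factor_anchor: float, rho: float) -> float:
    """Envelope factor after a 15-minute break.

    Removes the fraction ``rho`` of the growth accumulated during the block
    (end minus anchor); ``rho = 1`` recovers fully to the block's anchor,
    ``rho = 0`` keeps the full creep.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("recovery fraction must lie in [0, 1]")
    return envelope_factor_end - rho * (envelope_factor_end - envelope_factor_anchor)


def random_loop_params(
    rng: np.random.Generator,
    amplitude_range=(4.0, 10.0),
    slope_range=(2.0, 3.0),
    center_inner: float = 0.8,
    width_range=(0.3, 0.4),
) -> HysteresisParams:
    """Draw random, well-identified loop parameters for fit benchmarks.

    Slopes and centers are kept steep/central enough that the loop is close
    to its asymptotes at ±7.5 Nm, which makes the generating parameters
    recoverable from sampled loops; amplitudes span the physiological RoM
    range of lumbar segments.
    """
    B = rng.uniform(*amplitude_range)
    A = -rng.uniform(*amplitude_range)
    a = rng.uniform(*slope_range, 4)
    m1 = rng.uniform(-center_inner, 0.0, 2)
    m2 = rng.uniform(0.0, center_inner, 2)
    w = rng.uniform(*width_range)
    return HysteresisParams(
        A, B,
        a[0], m1[0] - w, a[1], m2[0] - w,   # upper branch shifted left
        a[2], m1[1] + w, a[3], m2[1] + w,   # lower branch shifted right
    )


def make_profile(config: GeneratorConfig, specimen_id: str, rng: np.random.Generator) -> SpecimenProfile:
    amp = float(np.exp(rng.normal(0.0, config.specimen_amp_sigma)))
    slope = float(np.exp(rng.normal(0.0, config.specimen_shape_sigma)))
    shift = float(rng.normal(0.0, config.specimen_center_sigma))
    bases = {}
    for d, p in config.base_params.items():
        bases[d] = replace(
            p,
            A=p.A * amp, B=p.B * amp,
            a1_u=p.a1_u * slope, a2_u=p.a2_u * slope,
            a1_l=p.a1_l * slope, a2_l=p.a2_l * slope,
            m1_u=p.m1_u + shift, m2_u=p.m2_u + shift,
            m1_l=p.m1_l + shift, m2_l=p.m2_l + shift,
        )
    gain = float(np.exp(rng.normal(0.0, config.creep_jitter_sigma)))
    return SpecimenProfile(specimen_id, config.temperature_group, bases, gain)


def _jitter_shapes(p: HysteresisParams, slope_sigma: float, center_sigma: float,
                   rng: np.random.Generator) -> HysteresisParams:
    if slope_sigma == 0 and center_sigma == 0:
        return p
    sl = np.exp(rng.normal(0.0, slope_sigma, 4))
    ce = rng.normal(0.0, center_sigma, 4)
    return replace(
        p,
        a1_u=p.a1_u * sl[0], a2_u=p.a2_u * sl[1], a1_l=p.a1_l * sl[2], a2_l=p.a2_l * sl[3],
        m1_u=p.m1_u + ce[0], m2_u=p.m2_u + ce[1], m1_l=p.m1_l + ce[2], m2_l=p.m2_l + ce[3],
    )


def generate_sequence(
    profile: SpecimenProfile,
    config: GeneratorConfig,
    direction: str,
    s: int,
    envelope_anchor: float,
    rng: np.random.Generator,
    return_loops: bool = False,
):
    """Generate one 30-minute loading block of one specimen.

    ``envelope_anchor`` is the cumulative envelope factor Q_s at the block's
    anchor cycle (1.0 for a fresh specimen).  Returns
    ``(CycleSequence, envelope_factor_after_break, loops)``; the sequence's
    ``extra`` dict records the block's start hour, the true creep gain and the
    post-break third-cycle RoM used for r_break.
    """
    K = int(config.cycles_per_sequence[direction])
    c_s = config.creep_gain * decay_factor(s, config) * profile.creep_gain_factor
    c_s *= float(np.exp(rng.normal(0.0, config.creep_jitter_sigma / 2)))
    base = _jitter_shapes(
        profile.base_params[direction], config.sequence_shape_sigma, 0.0, rng
    )

    cycles: list[HysteresisParams] = []
    loops: list[MomentRomLoop] = []
    for k in range(1, K + 1):
        factor = envelope_anchor * float(_saturating(k, c_s, config.creep_rate))
        p = base.scaled_envelope(factor)
        p = _jitter_shapes(p, config.cycle_shape_sigma, config.cycle_center_sigma, rng)
        if config.cycle_rom_sigma > 0:
            dA, dB = rng.normal(0.0, config.cycle_rom_sigma, 2)
            new_A, new_B = p.A + dA, p.B + dB
            if new_A < new_B:  # tiny noise cannot be allowed to invert the envelope
                p = replace(p, A=new_A, B=new_B)
        if config.emit == "fit" or return_loops:
            loop = sample_loop(p, noise_sigma=config.noise_sigma, rng=rng, cycle_index=k)
            loops.append(loop)
            if config.emit == "fit":
                p = fit_hysteresis(loop).params
        cycles.append(p)

    factor_end = envelope_anchor * float(_saturating(K, c_s, config.creep_rate))
    factor_recovered = apply_break_recovery(factor_end, envelope_anchor, config.recovery_fraction)
    rom_3_break = base.scaled_envelope(factor_recovered).rom_at(7.5, "upper")

    seq = CycleSequence(
        sequence_id=f"{profile.specimen_id}-{direction}-s{s}",
        specimen_id=profile.specimen_id,
        direction=direction,
        temperature=profile.temperature,
        sequence_index=s,
        tau_t=0.0,
        cycles=cycles,
        cycle_indices=list(range(1, K + 1)),
        extra={
            "start_hour": start_hour(direction, s),
            "rom_3_break": rom_3_break,
            "creep_gain_true": c_s,
        },
    )
    return seq, factor_recovered, loops


def generate_specimen(profile: SpecimenProfile, config: GeneratorConfig,
                      rng: np.random.Generator) -> list[CycleSequence]:
    """All blocks (directions × sequence indices) of one specimen."""
    out = []
    for direction in config.directions:
        anchor = 1.0
        for s in range(1, config.sequences_per_direction + 1):
            seq, anchor, _ = generate_sequence(profile, config, direction, s, anchor, rng)
            out.append(seq)
    return out


def generate_group(config: GeneratorConfig, rng: np.random.Generator | None = None) -> list[CycleSequence]:
    """Generate one temperature group: all specimens, directions, blocks."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    sequences = []
    for i in range(config.n_specimens):
        profile = make_profile(config, f"{config.temperature_group}{i + 1:03d}", rng)
        sequences.extend(generate_specimen(profile, config, rng))
    return sequences


def sequence_ratios(seq: CycleSequence) -> tuple[float, float | None]:
    """(r_load, r_break) of a block from its cycles and post-break RoM."""
    trace = seq.rom_trace(7.5, "upper")
    idx = {k: i for i, k in enumerate(seq.cycle_indices)}
    if 3 not in idx:
        raise ValueError("sequence lacks cycle 3; cannot form r_load")
    rom3 = trace[idx[3]]
    rom30 = trace[-1]
    r_load = float(rom3 / rom30)
    r_break = None
    if "rom_3_break" in seq.extra:
        r_break = float(rom30 / seq.extra["rom_3_break"])
    return r_load, r_break


def flip_params(p: HysteresisParams) -> HysteresisParams:
    """Point-mirror a loop's parameters: RoM'(m) = −RoM(−m).

    Closed form: A' = −B, B' = −A, branch roles exchange, and within each
    branch (a1', m1', a2', m2') = (a2, −m2, a1, −m1).  Verified in tests
    against the sampled mirror.
    """
    def mirror(branch):
        a1, m1, a2, m2 = branch
        return a2, -m2, a1, -m1

    u = mirror(p.branch("lower"))  # mirrored lower becomes the new upper
    lo = mirror(p.branch("upper"))
    return HysteresisParams(-p.B, -p.A, *u, *lo)


def flip_sequence(seq: CycleSequence) -> CycleSequence:
    """Sagittal-symmetry augmented copy of an LB or AR sequence."""
    if seq.direction == "FE":
        raise ValueError("FE is sagittally symmetric already; flipping applies to LB/AR")
    return replace(
        seq,
        sequence_id=seq.sequence_id + "-flip",
        cycles=[flip_params(p) for p in seq.cycles],
        flipped=True,
        extra=dict(seq.extra),
    )


def assign_tau_t(sequences: list[CycleSequence]) -> list[CycleSequence]:
    """Set τ_t = (group Kendall τ of r_load vs. total testing time) × start hour.

    The correlation is computed per temperature group from the sequences
    themselves (flipped copies excluded from the correlation, then given the
    τ_t of their source block's group).
    """
    by_temp: dict[str, list[int]] = {}
    for i, seq in enumerate(sequences):
        if not seq.flipped:
            by_temp.setdefault(seq.temperature, []).append(i)
    tau_by_temp = {}
    for temp, idxs in by_temp.items():
        r_loads = [sequence_ratios(sequences[i])[0] for i in idxs]
        hours = [sequences[i].extra.get("start_hour", start_hour(sequences[i].direction, sequences[i].sequence_index)) for i in idxs]
        tau_by_temp[temp] = kendall_tau(hours, r_loads, group_label=temp).tau
    out = []
    for seq in sequences:
        hour = seq.extra.get("start_hour", start_hour(seq.direction, seq.sequence_index))
        out.append(seq.with_tau_t(tau_by_temp[seq.temperature] * hour))
    return out


def _drop_first_cycle(seq: CycleSequence) -> CycleSequence:
    if seq.cycle_indices and seq.cycle_indices[0] == 1:
        return replace(seq, cycles=seq.cycles[1:], cycle_indices=seq.cycle_indices[1:])
    return seq


def build_dataset(
    configs: list[GeneratorConfig] | None = None,
    seed: int = 0,
    n_train: int = 116,
    n_validation: int = 9,
) -> tuple[list[CycleSequence], DatasetSplit]:
    """Build the full synthetic dataset with augmentation and split.

    Defaults to 3 BT + 3 RT specimens × 3 directions × 6 blocks plus flipped
    LB/AR copies (180 sequences, the scale of the reference dataset).  The
    preconditioning first cycle is dropped, τ_t is assigned per group, and
    whole sequences are shuffled into train/validation/test (remainder) by a
    seeded permutation.
    """
    if configs is None:
        configs = [
            GeneratorConfig.for_temperature("BT", seed=seed),
            GeneratorConfig.for_temperature("RT", seed=seed + 1),
        ]
    rng = np.random.default_rng(seed)
    sequences: list[CycleSequence] = []
    for cfg in configs:
        sequences.extend(generate_group(cfg, np.random.default_rng(cfg.seed)))
    flips = [flip_sequence(s) for s in sequences if s.direction in ("LB", "AR")]
    sequences = sequences + flips
    sequences = assign_tau_t(sequences)
    sequences = [_drop_first_cycle(s) for s in sequences]

    n = len(sequences)
    if n_train + n_validation > n:
        raise ValueError(f"requested split ({n_train}+{n_validation}) exceeds dataset size {n}")
    order = rng.permutation(n)
    ids = [sequences[i].sequence_id for i in order]
    split = DatasetSplit(
        train=tuple(ids[:n_train]),
        validation=tuple(ids[n_train:n_train + n_validation]),
        test=tuple(ids[n_train + n_validation:]),
    )
    return sequences, split
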