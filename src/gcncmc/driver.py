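"""Campaign orchestration: GCMC/MD and GCNCMC/MD cycles, equilibration.

A campaign alternates a move block with a stretch of Langevin MD: one
gradual (NCMC) move per iteration, or a batch of instantaneous GCMC moves.
A frame is recorded at the end of every iteration regardless of whether
the move was accepted.  Computational cost is accounted in force
evaluations — one per MD step (normal MD or NCMC propagation), one per
instantaneous GCMC move, and one per NCMC perturbation-energy evaluation
(the latter counting choice is flagged in reports).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import BAR_TO_KCAL_MOL_A3
from .dynamics import IntegratorSettings, baoab_step
from .errors import ConfigurationError
from .grand_moves import (AdamsParameters, GCRegion, MoveRecord,
                          attempt_instantaneous_move, region_members)
from .model import ParticleSystem, total_energy
from .ncmc import NCMCProtocol, attempt_ncmc_move


@dataclass
class Frame:
    """Lightweight per-iteration observation used by the analysis module."""

    iteration: int
    box: np.ndarray
    primary_positions: np.ndarray  # (n_real_movable, 3) primary-site coords
    region_count: int
    align_positions: np.ndarray | None = None  # reference-site coords for alignment


@dataclass
class CampaignStats:
    """Counters and per-move records accumulated over a campaign."""

    records: list[MoveRecord] = field(default_factory=list)
    frames: list[Frame] = field(default_factory=list)
    force_evaluations: int = 0
    md_steps_total: int = 0
    perturbation_evaluations: int = 0
    attempted: dict = field(default_factory=lambda: {"insert": 0, "delete": 0})
    accepted: dict = field(default_factory=lambda: {"insert": 0, "delete": 0})

    def add_record(self, rec: MoveRecord) -> None:
        self.records.append(rec)
        self.attempted[rec.kind] += 1
        if rec.accepted:
            self.accepted[rec.kind] += 1

    def summary(self) -> dict:
        n_att = sum(self.attempted.values())
        n_acc = sum(self.accepted.values())
        return {
            "moves_attempted": n_att,
            "moves_accepted": n_acc,
            "acceptance_rate": (n_acc / n_att) if n_att else None,
            "attempted_by_kind": dict(self.attempted),
            "accepted_by_kind": dict(self.accepted),
            "force_evaluations": self.force_evaluations,
            "md_steps_total": self.md_steps_total,
            "perturbation_evaluations": self.perturbation_evaluations,
            "frames": len(self.frames),
            "note": "perturbation energy evaluations are counted as force evaluations",
        }


def acceptance_rate(stats: CampaignStats, method: str | None = None,
                    kind: str | None = None) -> float | None:
    """Accepted/attempted over the recorded moves (auto-rejections count as
    attempts); ``None`` when nothing matching was attempted."""
    recs = [r for r in stats.records
            if (method is None or r.method == method)
            and (kind is None or r.kind == kind)]
    if not recs:
        return None
    return sum(r.accepted for r in recs) / len(recs)


@dataclass
class CampaignConfig:
    """Everything needed to reproduce a campaign from its seed."""

    method: str  # "gcmc" | "gcncmc"
    region: GCRegion
    adams: AdamsParameters
    iterations: int
    md_steps: int  # MD steps between move blocks
    seed: int = 0
    moves_per_batch: int = 20  # instantaneous moves per iteration (gcmc)
    protocol: NCMCProtocol | None = None  # required for gcncmc
    settings: IntegratorSettings = field(default_factory=IntegratorSettings)
    align_sites: tuple[int, ...] = ()  # site indices recorded for frame alignment

    def __post_init__(self):
        if self.method not in ("gcmc", "gcncmc"):
            raise ConfigurationError(f"unknown method {self.method!r}")
        if self.method == "gcncmc" and self.protocol is None:
            raise ConfigurationError("gcncmc campaigns require an NCMC protocol")
        if self.iterations < 0 or self.md_steps < 0 or self.moves_per_batch < 1:
            raise ConfigurationError("invalid campaign counts")


class Campaign:
    """A running campaign holding the system and both rng streams.

    ``run`` may be called repeatedly; chaining two runs of k iterations is
    identical to one run of 2k (restartability).
    """

    def __init__(self, config: CampaignConfig, system: ParticleSystem):
        self.config = config
        self.system = system
        root = np.random.default_rng(config.seed)
        self.proposal_rng, self.md_rng = root.spawn(2)
        self.stats = CampaignStats()
        self._iteration = 0

    def _record_frame(self) -> None:
        cfg = self.config
        ids = self.system.real_molecule_ids(species=cfg.region.species)
        prim = np.array([self.system.primary_position(i) for i in ids]).reshape(-1, 3)
        align = None
        if cfg.align_sites:
            align = self.system.positions[np.asarray(cfg.align_sites)].copy()
        self.stats.frames.append(Frame(
            iteration=self._iteration,
            box=self.system.box.copy(),
            primary_positions=prim,
            region_count=len(region_members(self.system, cfg.region)),
            align_positions=align,
        ))

    def _move_block(self) -> None:
        cfg, stats = self.config, self.stats
        if cfg.method == "gcmc":
            for _ in range(cfg.moves_per_batch):
                rec = attempt_instantaneous_move(
                    self.system, cfg.region, cfg.adams, self.proposal_rng)
                stats.add_record(rec)
                stats.force_evaluations += 1
        else:
            rec = attempt_ncmc_move(
                self.system, cfg.region, cfg.adams, cfg.protocol,
                cfg.settings, self.proposal_rng, md_rng=self.md_rng)
            stats.add_record(rec)
            stats.force_evaluations += rec.force_evaluations
            if rec.perturbation_du is not None:
                stats.perturbation_evaluations += len(rec.perturbation_du)
            if rec.accepted:
                stats.md_steps_total += cfg.protocol.total_md_steps

    def run(self, iterations: int | None = None) -> CampaignStats:
        cfg = self.config
        n = cfg.iterations if iterations is None else iterations
        for _ in range(n):
            self._iteration += 1
            self._move_block()
            for _ in range(cfg.md_steps):
                baoab_step(self.system, cfg.settings, self.md_rng)
            self.stats.force_evaluations += cfg.md_steps
            self.stats.md_steps_total += cfg.md_steps
            self._record_frame()
        return self.stats


def run_campaign(config: CampaignConfig, system: ParticleSystem) -> CampaignStats:
    """Run a full campaign; fully reproducible from ``config.seed``."""
    return Campaign(config, system).run()


# ---------------------------------------------------------------------------
# equilibration
# ---------------------------------------------------------------------------

def monte_carlo_volume_move(system: ParticleSystem, pressure_bar: float, rng,
                            max_frac: float = 0.02) -> bool:
    """Isotropic NPT volume move scaling molecular centroids; Metropolis test
    on exp(−β(ΔU + PΔV) + N ln(V'/V)).  Returns True if accepted."""
    V = float(np.prod(system.box))
    dV = (2.0 * rng.random() - 1.0) * max_frac * V
    V_new = V + dV
    if V_new <= 0:
        return False
    s = (V_new / V) ** (1.0 / 3.0)
    if np.any(system.box * s <= 2.0 * system.cutoff):
        return False  # the cutoff no longer fits; reject
    mol_ids = [i for i, m in enumerate(system.molecules) if m.real and not m.frozen]
    e_old = total_energy(system)
    old_positions = system.positions.copy()
    old_box = system.box.copy()
    for i in mol_ids:
        sl = system.mol_slice(i)
        centroid = system.positions[sl].mean(axis=0)
        system.positions[sl] += (s - 1.0) * centroid
    system.box = system.box * s
    system.invalidate_forces()
    e_new = total_energy(system)
    beta = system.beta()
    p = pressure_bar * BAR_TO_KCAL_MOL_A3
    log_acc = -beta * (e_new - e_old + p * dV) + len(mol_ids) * math.log(V_new / V)
    if math.log(max(rng.random(), 1e-300)) < log_acc:
        system.tracked_energy = e_new
        return True
    system.positions = old_positions
    system.box = old_box
    system.invalidate_forces()
    return False


def _scaled(n: int, factor: float) -> int:
    return int(round(n * factor))


def equilibrate(system: ParticleSystem, region: GCRegion, adams: AdamsParameters,
                seed: int, reduction: float = 1.0,
                settings: IntegratorSettings | None = None,
                npt_pressure_bar: float | None = None) -> CampaignStats:
    """Staged equilibration: a burst of instantaneous GCMC, GCMC/MD cycles,
    an optional NPT stage (Monte Carlo volume moves at 1 bar interleaved
    with MD), then final GCMC/MD cycles.

    At ``reduction`` = 1 the stages attempt exactly 10,000 + 100×1000 +
    500×200 instantaneous moves; every stage count is scaled by the single
    ``reduction`` factor for desk-scale systems, and 0 skips equilibration
    entirely.
    """
    stats = CampaignStats()
    if reduction <= 0:
        return stats
    settings = settings or IntegratorSettings(temperature=system.temperature)
    root = np.random.default_rng(seed)
    prop_rng, md_rng = root.spawn(2)

    def gcmc_burst(n_moves):
        for _ in range(n_moves):
            rec = attempt_instantaneous_move(system, region, adams, prop_rng)
            stats.add_record(rec)
            stats.force_evaluations += 1

    # stage 1: initial GCMC burst to hydrate structural sites
    gcmc_burst(_scaled(10_000, reduction))

    # stage 2: GCMC/MD cycles (10 fs of MD = 5 steps at 2 fs)
    md_steps_2 = max(1, _scaled(5, reduction))
    for _ in range(_scaled(100, reduction)):
        gcmc_burst(_scaled(1000, reduction))
        for _ in range(md_steps_2):
            baoab_step(system, settings, md_rng)
        stats.md_steps_total += md_steps_2
        stats.force_evaluations += md_steps_2

    # stage 3: optional NPT (500 ps of MD with periodic volume moves)
    if npt_pressure_bar is not None:
        n_npt = _scaled(250_000, reduction)
        for step in range(n_npt):
            baoab_step(system, settings, md_rng)
            if (step + 1) % 25 == 0:
                monte_carlo_volume_move(system, npt_pressure_bar, prop_rng)
        stats.md_steps_total += n_npt
        stats.force_evaluations += n_npt

    # stage 4: final GCMC/MD cycles (1 ps MD + 200 GCMC moves per iteration)
    md_steps_4 = max(1, _scaled(500, reduction))
    for _ in range(_scaled(500, reduction)):
        for _ in range(md_steps_4):
            baoab_step(system, settings, md_rng)
        stats.md_steps_total += md_steps_4
        stats.force_evaluations += md_steps_4
        gcmc_burst(_scaled(200, reduction))

    return stats
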