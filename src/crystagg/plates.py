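"""Synthetic plate-reader and morphometry data generation.

Stands in for the study's raw data: whole plates of noisy turbidity
traces under factorial conditions (protein, inositol, redox), late-
addition protocols with a flagged dead-time gap, and two-class
lognormal particle-morphometry tables.  All generators are
deterministic given a seed; distinct wells draw from independent
substreams spawned from the design seed.

Noise model: multiplicative lognormal reading noise (σ default 2%,
plate-reader turbidity noise scales with signal) plus one additive
baseline offset per well ~ Normal(0, 0.005 AU).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AdditionEvent, TurbidityTrace, WellCondition
from .kinetics import AggregationModel, SimulationError, SystemState
from .params import RateParams, default_params

__all__ = [
    "NoiseModel",
    "PlateDesign",
    "make_plate",
    "late_addition_plate",
    "synth_morphometry",
    "write_plate_csv",
    "read_plate_csv",
    "write_morphometry_csv",
    "read_morphometry_csv",
]


class PlateIOError(ValueError):
    """Raised on malformed plate/morphometry CSV input."""


@dataclass(frozen=True)
class NoiseModel:
    """Plate-reader noise: multiplicative lognormal + per-well offset."""

    sigma_multiplicative: float = 0.02   # lognormal σ of each reading
    sigma_offset_AU: float = 0.005       # SD of the per-well baseline offset

    def apply(self, turbidity: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.sigma_multiplicative == 0 and self.sigma_offset_AU == 0:
            return turbidity.copy()
        offset = rng.normal(0.0, self.sigma_offset_AU) if self.sigma_offset_AU else 0.0
        mult = (rng.lognormal(0.0, self.sigma_multiplicative, size=turbidity.shape)
                if self.sigma_multiplicative else 1.0)
        return turbidity * mult + offset


@dataclass(frozen=True)
class PlateDesign:
    """A plate layout: wells, their conditions, and acquisition settings."""

    wells: tuple[tuple[str, WellCondition, int], ...]  # (well id, condition, replicates)
    duration_s: float = 16200.0     # 4.5 h incubation
    read_interval_s: float = 90.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [w for w, _, _ in self.wells]
        if len(ids) != len(set(ids)):
            raise ValueError("well ids must be unique")
        if self.duration_s <= 0 or self.read_interval_s <= 0:
            raise ValueError("duration and read interval must be positive")


def _well_rngs(design: PlateDesign, n: int) -> list[np.random.Generator]:
    children = np.random.SeedSequence(design.seed).spawn(n)
    return [np.random.default_rng(c) for c in children]


def make_plate(design: PlateDesign, params: RateParams | None = None) -> list[TurbidityTrace]:
    """Simulate every well×replicate of a plate.

    Returns one noisy trace per replicate (well ids suffixed ``_r1``,
    ``_r2``, ... when replicate count > 1).  Noise-free designs (σ=0)
    reproduce the kinetic model's output exactly.
    """
    params = default_params() if params is None else params
    jobs = [(wid, cond, r, reps) for wid, cond, reps in design.wells
            for r in range(reps)]
    rngs = _well_rngs(design, len(jobs))
    traces = []
    for (wid, cond, rep, reps), rng in zip(jobs, rngs):
        name = wid if reps == 1 else f"{wid}_r{rep + 1}"
        try:
            model = AggregationModel.from_condition(params, cond)
            if cond.events:
                traj = model.simulate_with_events(cond.events, design.duration_s,
                                                  design.read_interval_s)
            else:
                traj = model.simulate(design.duration_s, design.read_interval_s)
        except SimulationError as err:
            raise SimulationError(f"well {name}: {err}") from err
        trace = traj.turbidity(well=name, condition=cond)
        trace.turbidity = design.noise.apply(trace.turbidity, rng)
        if cond.events:
            gap = [int(np.searchsorted(trace.times, e.time_s, side="right"))
                   for e in cond.events]
            trace.flags["post_event_gap"] = [g for g in gap if g < len(trace)]
        traces.append(trace)
    return traces


def late_addition_plate(
    design: PlateDesign,
    addition_time_s: float,
    added_inositol_mM: list[float],
    added_volume_uL: float = 40.0,
    initial_volume_uL: float = 60.0,
    disruption_fraction: float = 0.0,
    params: RateParams | None = None,
) -> list[TurbidityTrace]:
    """Late-addition protocol: one arm per added-inositol level.

    Each base well of ``design`` is expanded into len(added_inositol_mM)
    arms; the sample aggregates undisturbed in ``initial_volume_uL``,
    then the addition is applied at ``addition_time_s`` and the
    incubation resumes.  The reading following the event carries a
    dead-time flag.
    """
    if not 0 <= addition_time_s <= design.duration_s:
        raise ValueError("addition_time_s must lie within the incubation")
    new_wells = []
    for wid, cond, reps in design.wells:
        base = WellCondition(**{**cond.__dict__, "events": ()})
        for ino in added_inositol_mM:
            ev = AdditionEvent(time_s=addition_time_s,
                               added_volume_uL=added_volume_uL,
                               added_inositol_mM=ino,
                               disruption_fraction=disruption_fraction)
            arm = WellCondition(**{**base.__dict__, "events": (ev,)})
            new_wells.append((f"{wid}_add{ino:g}", arm, reps))
    expanded = PlateDesign(wells=tuple(new_wells), duration_s=design.duration_s,
                           read_interval_s=design.read_interval_s,
                           noise=design.noise, seed=design.seed)
    # late additions run in the initial volume until the event
    params = default_params() if params is None else params
    traces = []
    jobs = [(wid, cond, r, reps) for wid, cond, reps in expanded.wells
            for r in range(reps)]
    rngs = _well_rngs(expanded, len(jobs))
    for (wid, cond, rep, reps), rng in zip(jobs, rngs):
        name = wid if reps == 1 else f"{wid}_r{rep + 1}"
        model = AggregationModel(params,
                                 SystemState.from_condition(cond, initial_volume_uL))
        traj = model.simulate_with_events(cond.events, expanded.duration_s,
                                          expanded.read_interval_s)
        trace = traj.turbidity(well=name, condition=cond)
        trace.turbidity = expanded.noise.apply(trace.turbidity, rng)
        gap = int(np.searchsorted(trace.times, addition_time_s, side="right"))
        trace.flags["post_event_gap"] = [gap] if gap < len(trace) else []
        traces.append(trace)
    return traces


# ---------------------------------------------------------------------------
# synthetic morphometry
# ---------------------------------------------------------------------------

def synth_morphometry(
    n_images: int = 30,
    treatments: tuple[float, ...] = (0.0,),
    class_mix: float = 0.6,
    extended_length_nm: tuple[float, float] = (120.0, 0.5),
    globular_size_nm: tuple[float, float] = (300.0, 0.6),
    particles_per_image: float = 8.0,
    treatment_effect=None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a two-class lognormal particle table.

    Per image the particle count is Poisson(``particles_per_image``);
    each particle is ``extended`` with probability ``class_mix`` else
    ``globular``.  Sizes are lognormal with the given (median, σ_log)
    per class — lengths in nm for extended particles, characteristic
    sizes in nm for globular ones.  ``treatment_effect`` maps a
    treatment label to a pair of multiplicative scale factors
    (extended, globular); identity when omitted.
    """
    if n_images <= 0 or particles_per_image <= 0:
        raise ValueError("n_images and particles_per_image must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    effect = treatment_effect or {}
    rows = []
    for trt in treatments:
        f_ext, f_glob = effect.get(trt, (1.0, 1.0))
        for img in range(n_images):
            image_id = f"trt{trt:g}_img{img:03d}"
            count = rng.poisson(particles_per_image)
            for _ in range(count):
                if rng.random() < class_mix:
                    med, sig = extended_length_nm
                    size = float(rng.lognormal(np.log(med * f_ext), sig))
                    cls = "extended"
                else:
                    med, sig = globular_size_nm
                    size = float(rng.lognormal(np.log(med * f_glob), sig))
                    cls = "globular"
                rows.append({"image_id": image_id, "class": cls,
                             "size": size, "treatment": trt})
    df = pd.DataFrame(rows, columns=["image_id", "class", "size", "treatment"])
    df.attrs["size_units"] = "nm"
    return df


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_PLATE_COLUMNS = ["time_s", "well", "protein_uM", "inositol_mM", "oxd",
                  "total_glutathione_mM", "turbidity_AU"]


def write_plate_csv(traces: list[TurbidityTrace], path) -> None:
    """Write traces in long format (one row per reading), UTF-8, comma-separated."""
    frames = []
    for tr in traces:
        c = tr.condition
        frames.append(pd.DataFrame({
            "time_s": tr.times,
            "well": tr.well,
            "protein_uM": c.protein_uM,
            "inositol_mM": c.inositol_mM,
            "oxd": c.oxd,
            "total_glutathione_mM": c.total_glutathione_mM,
            "turbidity_AU": tr.turbidity,
        }))
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format="%.12g", encoding="utf-8")


def read_plate_csv(path) -> list[TurbidityTrace]:
    """Read a long-format plate CSV back into traces (demultiplexed by well).

    Raises :class:`PlateIOError` naming the missing column or the line
    of the first non-monotone time stamp.
    """
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in _PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise PlateIOError(f"missing required column(s): {', '.join(missing)}")
    traces = []
    for well, grp in df.groupby("well", sort=False):
        t = grp["time_s"].to_numpy(dtype=float)
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            line = int(grp.index[bad[0] + 1]) + 2  # header + 1-based
            raise PlateIOError(f"non-monotone time for well {well!r} at line {line}")
        cond = WellCondition(
            protein_uM=float(grp["protein_uM"].iloc[0]),
            inositol_mM=float(grp["inositol_mM"].iloc[0]),
            oxd=float(grp["oxd"].iloc[0]),
            total_glutathione_mM=float(grp["total_glutathione_mM"].iloc[0]),
        )
        traces.append(TurbidityTrace(well=str(well), condition=cond, times=t,
                                     turbidity=grp["turbidity_AU"].to_numpy(dtype=float)))
    return traces


_MORPH_COLUMNS = ["image_id", "class", "size", "treatment"]


def write_morphometry_csv(records: pd.DataFrame, path) -> None:
    records[_MORPH_COLUMNS].to_csv(path, index=False, float_format="%.12g",
                                   encoding="utf-8")


def read_morphometry_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in _MORPH_COLUMNS if c not in df.columns]
    if missing:
        raise PlateIOError(f"missing required column(s): {', '.join(missing)}")
    return df
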