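"""Deployed-trap duty cycle: change-triggered uploads and battery-life estimation.

An e-trap wakes once per day, loads the counting model, photographs its
interior (at night, with flash), infers the insect count, and uploads the
image and count to a server *only if the count differs from the previous
day's* — on a sticky trap counts change rarely, so this trigger saves nearly
all of the costly radio traffic.  The very first observation always uploads so
the server has a defined initial state.  The device then returns to deep
sleep.

Energy accounting uses a per-phase consumption profile (average current and
duration for capture-with-flash, inference, store+upload, and housekeeping,
plus the deep-sleep current): the active window displaces sleep time within
the 86,400-second day, and battery life in days is capacity divided by the
daily draw.  Profiles for four reference devices ship as YAML fixtures (an
ESP32-CAM microcontroller, a Raspberry Pi 4, and a Coral mini dev board with
and without its TPU delegate); the estimate is a maximum-consumption scenario
in which the upload happens every day.

Hardware I/O is out of scope: the camera is any scene source and the upload
transport is an injected interface whose default mock just records payloads.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from PIL import Image

from .evaluator import round_prediction

__all__ = [
    "Phase",
    "ConsumptionProfile",
    "TrapState",
    "MockTransport",
    "load_profile",
    "should_upload",
    "daily_consumption_mAh",
    "estimate_battery_life",
    "run_daily_cycle",
    "simulate_deployment",
    "StickyTrapSceneProvider",
]

SECONDS_PER_DAY = 86_400.0


@dataclass(frozen=True)
class Phase:
    name: str
    avg_current_mA: float
    duration_s: float


@dataclass
class ConsumptionProfile:
    """Per-phase current/duration figures plus battery capacity."""

    name: str
    sleep_current_mA: float
    phases: list[Phase]
    battery_capacity_mAh: float
    cycles_per_day: int = 1

    def __post_init__(self) -> None:
        if self.battery_capacity_mAh <= 0:
            raise ValueError("battery capacity must be positive")
        if self.cycles_per_day < 0:
            raise ValueError("cycles_per_day must be >= 0")
        if self.sleep_current_mA < 0 or any(
            p.avg_current_mA < 0 or p.duration_s < 0 for p in self.phases
        ):
            raise ValueError("currents and durations must be non-negative")

    @property
    def active_seconds(self) -> float:
        return sum(p.duration_s for p in self.phases)

    @property
    def active_charge_mAs(self) -> float:
        return sum(p.avg_current_mA * p.duration_s for p in self.phases)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ConsumptionProfile":
        d = yaml.safe_load(Path(path).read_text())
        return cls(
            name=d["name"],
            sleep_current_mA=float(d["sleep_current_mA"]),
            phases=[Phase(p["name"], float(p["avg_current_mA"]), float(p["duration_s"])) for p in d["phases"]],
            battery_capacity_mAh=float(d["battery_capacity_mAh"]),
            cycles_per_day=int(d.get("cycles_per_day", 1)),
        )

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def load_profile(name: str) -> ConsumptionProfile:
    """Load one of the bundled device profiles: esp32, rpi4, coral, coral_tpu."""
    ref = resources.files("trapcount") / "profiles" / f"{name}.yaml"
    with resources.as_file(ref) as p:
        return ConsumptionProfile.from_yaml(p)


def daily_consumption_mAh(profile: ConsumptionProfile) -> float:
    """Charge drawn per day: sleep over the remainder of the day plus the
    active phases, ``cycles_per_day`` times."""
    active = profile.cycles_per_day * profile.active_seconds
    if active > SECONDS_PER_DAY:
        raise ValueError("active time exceeds one day")
    sleep_mAs = profile.sleep_current_mA * (SECONDS_PER_DAY - active)
    return (sleep_mAs + profile.cycles_per_day * profile.active_charge_mAs) / 3600.0


def estimate_battery_life(profile: ConsumptionProfile) -> float:
    """Expected lifetime in days; ``inf`` if the profile draws nothing."""
    daily = daily_consumption_mAh(profile)
    if daily == 0.0:
        return math.inf
    return profile.battery_capacity_mAh / daily


# ---------------------------------------------------------------------------
# Duty cycle
# ---------------------------------------------------------------------------

def should_upload(prev_count: int | None, new_count: int) -> bool:
    """Upload iff the count changed since yesterday (first report always goes)."""
    if new_count < 0:
        raise ValueError("counts must be non-negative")
    return prev_count is None or new_count != prev_count


@dataclass
class TrapState:
    day_index: int = 0
    last_count: int | None = None
    last_image_ref: str | None = None
    upload_log: list[tuple[int, int, bool]] = field(default_factory=list)  # (day, count, uploaded)


class MockTransport:
    """Stand-in for the WiFi/HTTP upload path: records POST payloads, and
    optionally writes them to disk as JSON metadata plus a PNG."""

    def __init__(self, out_dir: str | Path | None = None):
        self.posts: list[dict] = []
        self.out_dir = Path(out_dir) if out_dir else None
        if self.out_dir:
            self.out_dir.mkdir(parents=True, exist_ok=True)

    def post(self, payload: dict) -> None:
        self.posts.append(payload)
        if self.out_dir:
            day = payload["day"]
            meta = {k: v for k, v in payload.items() if k != "image"}
            (self.out_dir / f"upload_day{day:04d}.json").write_text(json.dumps(meta))
            if payload.get("image") is not None:
                Image.fromarray(payload["image"], mode="L").save(
                    self.out_dir / f"upload_day{day:04d}.png"
                )


def run_daily_cycle(state: TrapState, image: np.ndarray, model, transport=None) -> tuple[TrapState, bool]:
    """One wake cycle: load model, capture, infer, conditionally upload, store,
    sleep.  ``model`` needs a ``predict(image) -> raw scalar`` method.  A
    failed inference is logged and leaves everything but the day counter
    unchanged."""
    day = state.day_index
    try:
        count = round_prediction(float(np.asarray(model.predict(image)).ravel()[0]))
    except Exception:
        state.day_index = day + 1
        state.upload_log.append((day, -1, False))
        return state, False
    uploaded = should_upload(state.last_count, count)
    if uploaded and transport is not None:
        transport.post({"day": day, "count": count, "image": image})
    state.upload_log.append((day, count, uploaded))
    state.last_count = count
    state.last_image_ref = f"day{day:04d}.png"
    state.day_index = day + 1
    return state, uploaded


class StickyTrapSceneProvider:
    """Renders the trap floor day by day as insects accumulate.

    Insects on a sticky trap stay where they landed, so the provider keeps
    yesterday's placements and only adds sprites when the schedule's count
    rises.  Requires a monotone non-decreasing schedule.
    """

    def __init__(self, config, bank, seed: int = 0, split: str = "test"):
        from . import scene_composer as sc

        self._sc = sc
        self.config = config
        self.bank = bank
        self.backgrounds = sc.make_backgrounds(config)
        self.pool = bank.indices_for(split)
        self.rng = np.random.default_rng(np.random.SeedSequence([seed, 31337]))
        self._placed: list[tuple[int, float, tuple[int, int], np.ndarray, np.ndarray]] = []
        self._occupancy = np.zeros_like(self.backgrounds[0], dtype=bool)

    def scene_for(self, count: int) -> np.ndarray:
        if count > self.config.max_count:
            raise ValueError("invalid class range: scheduled count exceeds max_count")
        if count < len(self._placed):
            raise ValueError("sticky-trap schedule must be non-decreasing")
        while len(self._placed) < count:
            self._add_sprite()
        bg = self.backgrounds[0].astype(np.float32) / 255.0
        for _, _, (r, c), pix, mask in self._placed:
            region = bg[r:r + mask.shape[0], c:c + mask.shape[1]]
            region[mask] = pix[mask]
        return np.clip(np.round(bg * 255), 0, 255).astype(np.uint8)

    def _add_sprite(self) -> None:
        sc = self._sc
        idx = int(self.rng.choice(self.pool))
        sprite = self.bank.sprites[idx]
        angle = float(self.rng.uniform(0, 360))
        pix, mask = sc._rotate_sprite(sprite, angle)
        h, w = mask.shape
        hb, wb = self._occupancy.shape
        m = self.config.separation_px
        dil = ndimage.binary_dilation(np.pad(mask, m), np.ones((3, 3), bool), iterations=m)
        for _ in range(self.config.max_attempts):
            r = int(self.rng.integers(0, hb - h + 1))
            c = int(self.rng.integers(0, wb - w + 1))
            r0, c0 = max(r - m, 0), max(c - m, 0)
            r1, c1 = min(r + h + m, hb), min(c + w + m, wb)
            sub = dil[m + (r0 - r): m + (r1 - r), m + (c0 - c): m + (c1 - c)]
            if not (self._occupancy[r0:r1, c0:c1] & sub).any():
                self._occupancy[r:r + h, c:c + w] |= mask
                self._placed.append((idx, angle, (r, c), pix, mask))
                return
        raise sc.SceneOvercrowdedError("scene overcrowded: trap floor is full")


@dataclass
class DeploymentLog:
    rows: list[dict]
    daily_mAh: float

    @property
    def n_uploads(self) -> int:
        return sum(1 for r in self.rows if r["uploaded"])

    @property
    def total_energy_mAh(self) -> float:
        return self.rows[-1]["cumulative_mAh"] if self.rows else 0.0

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.rows).to_csv(path, index=False)


def simulate_deployment(
    arrival_schedule,
    model,
    scene_provider,
    profile: ConsumptionProfile,
    transport: MockTransport | None = None,
) -> DeploymentLog:
    """Run the daily duty cycle over a per-day true-count schedule.

    ``scene_provider`` maps a day's true count to a rendered trap image (see
    :class:`StickyTrapSceneProvider`); an oracle counter can be passed as
    ``model`` to exercise the trigger logic alone.
    """
    transport = transport or MockTransport()
    state = TrapState()
    daily = daily_consumption_mAh(profile)
    rows = []
    for day, true_count in enumerate(arrival_schedule):
        image = scene_provider.scene_for(int(true_count))
        state, uploaded = run_daily_cycle(state, image, model, transport)
        _, inferred, _ = state.upload_log[-1]
        rows.append(
            {
                "day": day,
                "true_count": int(true_count),
                "inferred_count": inferred,
                "uploaded": uploaded,
                "cumulative_mAh": (day + 1) * daily,
            }
        )
    return DeploymentLog(rows=rows, daily_mAh=daily)
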