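"""Named neoadjuvant schedule presets and config-file I/O.

The experimental arms use a fixed 14-day presurgical window: daily sunitinib
at 60 mg/kg for the first 3, 7 or 14 days of the window (vehicle for the
rest), or a 120 mg/kg loading block of 3 days followed by 60 mg/kg for 0, 4,
8 or 11 days.  Surgery is at day 34 (calibration groups) or day 38
(validation groups) post-implantation.  Preset labels follow the study's
shorthand, e.g. ``Su60(14D)`` or ``Su120(3D)+Su60(8D)``; ``vehicle`` is the
untreated control arm.
"""

from __future__ import annotations

import re

import yaml

from .growth import Schedule

__all__ = ["schedule_preset", "preset_names", "daily_schedule", "load_schedule",
           "dump_schedule", "PRESURGICAL_WINDOW_DAYS"]

#: length of the presurgical treatment window (days)
PRESURGICAL_WINDOW_DAYS = 14

# canonical name -> list of (dose mg/kg, n consecutive days) blocks
_ARMS: dict[str, list[tuple[float, int]]] = {
    "vehicle": [],
    "Su60(3D)": [(60.0, 3)],
    "Su60(7D)": [(60.0, 7)],
    "Su60(14D)": [(60.0, 14)],
    "Su120(3D)": [(120.0, 3)],
    "Su120(3D)+Su60(4D)": [(120.0, 3), (60.0, 4)],
    "Su120(3D)+Su60(8D)": [(120.0, 3), (60.0, 8)],
    "Su120(3D)+Su60(11D)": [(120.0, 3), (60.0, 11)],
}


def preset_names() -> list[str]:
    return list(_ARMS)


def _canonical(name: str) -> str:
    key = re.sub(r"\s+", "", name).lower()
    for canon in _ARMS:
        if re.sub(r"\s+", "", canon).lower() == key:
            return canon
    raise KeyError(f"unknown schedule preset {name!r}; known: {', '.join(_ARMS)}")


def schedule_preset(name: str, surgery_day: float = 34.0, horizon: float = 85.0) -> Schedule:
    """Build a :class:`~metanat.growth.Schedule` for a named treatment arm.

    Doses start at ``surgery_day - 14`` (the presurgical window) and are
    given once daily block by block.
    """
    blocks = _ARMS[_canonical(name)]
    start = surgery_day - PRESURGICAL_WINDOW_DAYS
    doses, day = [], start
    for amount, ndays in blocks:
        for _ in range(ndays):
            doses.append((amount, day))
            day += 1.0
    return Schedule(doses=tuple(doses), resection_day=surgery_day, horizon=horizon)


def daily_schedule(dose: float, start_day: float, duration_days: int,
                   resection_day: float, horizon: float = 85.0) -> Schedule:
    """Daily dosing at ``dose`` mg/kg for ``duration_days`` days from
    ``start_day`` (used by the regimen-exploration grid)."""
    doses = tuple((dose, start_day + i) for i in range(duration_days))
    return Schedule(doses=doses, resection_day=resection_day, horizon=horizon)


def load_schedule(path) -> Schedule:
    """Read a schedule from a YAML file.

    Either ``{preset: Su60(14D), surgery_day: 34, horizon: 85}`` or an
    explicit ``{doses: [[60, 20], ...], resection_day: 34, horizon: 85}``.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if "preset" in cfg:
        return schedule_preset(cfg["preset"], cfg.get("surgery_day", 34.0),
                               cfg.get("horizon", 85.0))
    return Schedule(
        doses=tuple((float(d), float(t)) for d, t in cfg.get("doses", [])),
        resection_day=float(cfg["resection_day"]),
        horizon=float(cfg.get("horizon", 85.0)),
    )


def dump_schedule(sched: Schedule, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {"doses": [[d, t] for d, t in sched.doses],
             "resection_day": sched.resection_day, "horizon": sched.horizon},
            fh, sort_keys=False)
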