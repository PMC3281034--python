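"""Synthetic contact-diary generator with known mixing-type ground truth.

Emulates a cross-over diary study of adults who each keep a diary on three
days (Wednesday, Friday, Sunday) under three recording tools (pre-entry
questionnaire, paper diary, PDA diary).  The generator builds, for every
subject-day, a latent *mixing archetype* — a setting-dominated Dirichlet
component over the six setting categories — and then constructs visits whose
normalized person-contact-hours (PCH) profile tracks that archetype.  The
archetype per subject-day is recorded as ground truth so cluster-recovery
tests can score themselves.

Structure emulated, in generation order per subject-day:

1. archetype drawn from day-dependent mixing-type frequencies (work types
   are common on weekdays, social types on Sundays);
2. target profile ``w ~ Dirichlet(alpha_archetype)`` over the six settings;
3. settings present: home always; every other setting independently with a
   day-dependent presence probability; the archetype's own setting is
   forced present; ``w`` is renormalized over the present set;
4. a total daily PCH-setting budget ``T`` (log-normal, median 124
   person-hours); per present setting a stay duration (log-normal,
   setting-specific) — durations are rescaled if the day would exceed 24 h;
5. whole-setting headcount ``n_setting = round(w_s * T / duration)`` with
   unbiased stochastic rounding, so the expected normalized PCH-setting
   profile equals the (renormalized) archetype draw;
6. arm's-reach headcount via a setting-specific Beta ratio of
   ``n_setting``; with probability ``inconsistency_rate`` the
   subject-day-setting is made self-inconsistent (``n_reach > n_setting``),
   mimicking diarists' imperfect headcount estimates;
7. visits (a setting's stay is sometimes split into two diary pages) and
   encounters: each person within reach is conversed with independently,
   interaction time a Beta fraction of the stay, occasionally split into
   repeated encounters with the same contact;
8. per-tool views by independent per-visit thinning with setting-specific
   ascertainment probabilities (paper is the faithful reference; the PDA
   under-ascertains home and travel, the questionnaire under-ascertains
   unplanned retail/social/other presence).

All draws come from a single ``numpy.random.default_rng`` stream in a fixed
documented order, so a given seed yields a byte-identical dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .diary_model import (
    DAYS,
    SETTINGS,
    TOOLS,
    DiaryDataset,
    ENCOUNTER_COLUMNS,
    SUBJECT_COLUMNS,
    VISIT_COLUMNS,
)

__all__ = ["GeneratorConfig", "generate", "apply_tool_bias", "expected_profile"]


def _default_presence_prob() -> dict[str, dict[str, float]]:
    # Qualitative day effects: work collapses on Sunday, social rises.
    return {
        "Wed": {"home": 1.0, "other": 0.50, "retail": 0.55, "social": 0.45,
                "travel": 0.85, "work": 0.75},
        "Fri": {"home": 1.0, "other": 0.50, "retail": 0.60, "social": 0.55,
                "travel": 0.85, "work": 0.75},
        "Sun": {"home": 1.0, "other": 0.40, "retail": 0.50, "social": 0.65,
                "travel": 0.70, "work": 0.15},
    }


def _default_duration_params() -> dict[str, tuple[float, float]]:
    # (median hours, sigma of log): waking time at home dominates the day.
    return {
        "home": (13.0, 0.20),
        "other": (1.5, 0.40),
        "retail": (0.75, 0.40),
        "social": (2.5, 0.40),
        "travel": (1.0, 0.35),
        "work": (7.0, 0.25),
    }


def _default_headcount_params() -> dict[str, tuple[float, float]]:
    # Beta(a, b) for the ratio n_reach / n_setting: nearly everyone at home
    # is within reach, few of a shop's occupants are.
    return {
        "home": (8.0, 2.0),
        "other": (2.0, 5.0),
        "retail": (1.5, 8.0),
        "social": (3.0, 4.0),
        "travel": (3.0, 3.0),
        "work": (2.0, 6.0),
    }


def _default_archetype_weights() -> dict[str, np.ndarray]:
    # One setting-dominated Dirichlet component per setting category.
    weights = {}
    for i, s in enumerate(SETTINGS):
        alpha = np.full(len(SETTINGS), 0.8)
        alpha[i] = 12.0
        weights[s] = alpha
    return weights


def _default_day_archetype_probs() -> dict[str, dict[str, float]]:
    # Day-dependent mixing-type frequencies: home/work dominate weekdays,
    # home/social dominate Sundays; travel and retail types are rare.
    return {
        "Wed": {"home": 0.30, "other": 0.09, "retail": 0.07, "social": 0.14,
                "travel": 0.06, "work": 0.34},
        "Fri": {"home": 0.32, "other": 0.10, "retail": 0.08, "social": 0.18,
                "travel": 0.06, "work": 0.26},
        "Sun": {"home": 0.45, "other": 0.10, "retail": 0.09, "social": 0.28,
                "travel": 0.04, "work": 0.04},
    }


def _default_tool_bias() -> dict[str, dict[str, float]]:
    # Per-visit ascertainment probabilities.  Paper diaries are the faithful
    # reference; PDA diaries miss home and travel pages, the pre-entry
    # questionnaire misses unplanned retail/social/other presence.
    return {
        "paper": {s: 1.0 for s in SETTINGS},
        "pda": {"home": 0.85, "other": 0.95, "retail": 0.95, "social": 0.95,
                "travel": 0.60, "work": 0.95},
        "questionnaire": {"home": 1.0, "other": 0.70, "retail": 0.55,
                          "social": 0.60, "travel": 0.90, "work": 0.95},
    }


def _default_household_size_dist() -> dict[int, float]:
    # Median 3, IQR (2, 4) — small Australian-style households.
    return {1: 0.12, 2: 0.23, 3: 0.25, 4: 0.22, 5: 0.12, 6: 0.06}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic diary study.

    Defaults describe a 65-adult, 3-day, 3-tool cross-over study with
    universal home presence, day-dependent presence in the other five
    settings, six clearly separated setting-dominated mixing archetypes
    (dominant Dirichlet concentration 12 versus 0.8 elsewhere), a 7.5%
    headcount-inconsistency rate, and tool-specific under-ascertainment.
    """

    n_subjects: int = 65
    days: tuple[str, ...] = DAYS
    tools: tuple[str, ...] = TOOLS
    presence_prob: dict[str, dict[str, float]] = field(
        default_factory=_default_presence_prob
    )
    duration_params: dict[str, tuple[float, float]] = field(
        default_factory=_default_duration_params
    )
    headcount_params: dict[str, tuple[float, float]] = field(
        default_factory=_default_headcount_params
    )
    total_pch_median: float = 124.0  # person-hours of PCH-setting per day
    total_pch_sigma: float = 1.0  # sigma of log total
    inconsistency_rate: float = 0.075
    archetype_weights: dict[str, np.ndarray] = field(
        default_factory=_default_archetype_weights
    )
    day_archetype_probs: dict[str, dict[str, float]] = field(
        default_factory=_default_day_archetype_probs
    )
    tool_bias: dict[str, dict[str, float]] = field(default_factory=_default_tool_bias)
    household_size_dist: dict[int, float] = field(
        default_factory=_default_household_size_dist
    )
    visit_split_prob: float = 0.25
    talk_prob: float = 0.7  # P(a person within reach is conversed with)
    repeat_prob: float = 0.3  # P(a contact's interaction splits in two)
    interaction_frac: tuple[float, float] = (2.0, 2.0)  # Beta for time share
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for day in self.days:
            if day not in DAYS:
                raise ValueError(f"unknown day {day!r}")
            probs = self.presence_prob[day]
            if not np.isclose(probs["home"], 1.0):
                raise ValueError("presence_prob(day, home) must be 1")
            for s, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"presence_prob[{day}][{s}]={p} outside [0,1]")
        for tool in self.tools:
            if tool not in TOOLS:
                raise ValueError(f"unknown tool {tool!r}")
            for s, p in self.tool_bias[tool].items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"tool_bias[{tool}][{s}]={p} outside [0,1]")
        if not 0.0 <= self.inconsistency_rate <= 1.0:
            raise ValueError("inconsistency_rate outside [0,1]")
        for s, alpha in self.archetype_weights.items():
            alpha = np.asarray(alpha, dtype=float)
            if alpha.shape != (len(SETTINGS),) or (alpha <= 0).any():
                raise ValueError(f"archetype_weights[{s}] must be 6 positive values")
            if int(np.argmax(alpha)) != SETTINGS.index(s):
                raise ValueError(
                    f"archetype_weights[{s}] must be maximal on {s!r}"
                )
        for day in self.days:
            total = sum(self.day_archetype_probs[day].values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"day_archetype_probs[{day}] must sum to 1")
        if not all(p >= 0 for p in self.household_size_dist.values()):
            raise ValueError("household_size_dist probabilities must be >= 0")


def expected_profile(
    archetype_weights: Mapping[str, np.ndarray], setting: str
) -> np.ndarray:
    """Analytic mean profile of one archetype: alpha / sum(alpha).

    Returned in canonical setting order; shares sum to 1.
    """
    alpha = np.asarray(archetype_weights[setting], dtype=float)
    if (alpha <= 0).any():
        raise ValueError("concentration parameters must be positive")
    return alpha / alpha.sum()


def generate(
    config: GeneratorConfig | None = None, seed: int | None = None
) -> tuple[DiaryDataset, pd.DataFrame]:
    """Generate a synthetic diary dataset plus its archetype ground truth.

    Returns ``(dataset, truth)`` where ``truth`` has one row per
    subject-day with columns ``subject_id, day, true_mixing_type``.
    Identical (config, seed) pairs produce identical output.
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    subjects = _draw_subjects(config, rng)
    base_visits: list[dict] = []
    base_encounters: list[dict] = []
    truth_rows: list[dict] = []

    hh_size = dict(zip(subjects["subject_id"], subjects["household_size"]))

    for sid in subjects["subject_id"]:
        for day in config.days:
            archetype = _choice(rng, config.day_archetype_probs[day])
            truth_rows.append(
                {"subject_id": sid, "day": day, "true_mixing_type": archetype}
            )
            _generate_subject_day(
                config, rng, sid, day, archetype, hh_size[sid],
                base_visits, base_encounters,
            )

    base = DiaryDataset(
        subjects=subjects,
        visits=pd.DataFrame(base_visits, columns=VISIT_COLUMNS),
        encounters=pd.DataFrame(base_encounters, columns=ENCOUNTER_COLUMNS),
    )

    tool_frames_v = []
    tool_frames_e = []
    for tool in config.tools:
        view = _thin_view(base, tool, config.tool_bias[tool], rng)
        tool_frames_v.append(view.visits)
        tool_frames_e.append(view.encounters)

    dataset = DiaryDataset(
        subjects=subjects,
        visits=pd.concat(tool_frames_v, ignore_index=True)
        if tool_frames_v
        else base.visits.iloc[0:0],
        encounters=pd.concat(tool_frames_e, ignore_index=True)
        if tool_frames_e
        else base.encounters.iloc[0:0],
    )
    truth = pd.DataFrame(truth_rows, columns=["subject_id", "day", "true_mixing_type"])
    return dataset, truth


def apply_tool_bias(
    dataset: DiaryDataset,
    tool_bias: Mapping[str, float],
    seed: int,
    keep_min_one: bool = True,
) -> DiaryDataset:
    """Thin a single-tool diary view by per-setting ascertainment.

    Each visit is retained independently with ``tool_bias[setting]``;
    encounters of dropped visits are dropped.  With ``keep_min_one`` a
    subject-day whose visits were all dropped keeps its single most
    ascertainable visit, so a diary day never vanishes from the record.
    """
    for s, p in tool_bias.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"tool_bias[{s}]={p} outside [0,1]")
    rng = np.random.default_rng(seed)
    visits = dataset.visits.reset_index(drop=True)
    probs = visits["setting"].map(lambda s: tool_bias.get(s, 1.0)).to_numpy(float)
    keep = rng.random(len(visits)) < probs

    if keep_min_one and len(visits):
        kept = pd.Series(keep, index=visits.index)
        for (_, _), idx in visits.groupby(["subject_id", "day"]).groups.items():
            if not kept.loc[idx].any():
                sub = visits.loc[idx]
                best = sub.sort_values(
                    ["visit_id"], kind="stable"
                ).sort_values(
                    ["duration_h"], ascending=False, kind="stable"
                )
                best = best.loc[
                    best["setting"].map(lambda s: tool_bias.get(s, 1.0)).idxmax()
                ]
                kept.loc[best.name] = True
        keep = kept.to_numpy()

    new_visits = visits[keep].reset_index(drop=True)
    key_cols = ["subject_id", "day", "tool", "visit_id"]
    kept_keys = set(map(tuple, new_visits[key_cols].to_numpy()))
    enc = dataset.encounters
    enc_keep = [tuple(row) in kept_keys for row in enc[key_cols].to_numpy()]
    new_enc = enc[enc_keep].reset_index(drop=True)
    return DiaryDataset(
        subjects=dataset.subjects.copy(), visits=new_visits, encounters=new_enc
    )


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------


def _draw_subjects(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    width = max(2, len(str(config.n_subjects)))
    sizes = np.array(sorted(config.household_size_dist))
    size_p = np.array([config.household_size_dist[s] for s in sizes], dtype=float)
    size_p = size_p / size_p.sum()
    rows = []
    for i in range(config.n_subjects):
        hh = int(rng.choice(sizes, p=size_p))
        max_children = max(hh - 1, 0)
        n_children = int(rng.binomial(max_children, 0.4)) if max_children else 0
        rows.append(
            {
                "subject_id": f"S{i + 1:0{width}d}",
                "age": int(rng.integers(20, 71)),
                "sex": "female" if rng.random() < 0.5 else "male",
                "household_size": hh,
                "n_children": n_children,
            }
        )
    return pd.DataFrame(rows, columns=SUBJECT_COLUMNS)


def _choice(rng: np.random.Generator, probs: Mapping[str, float]) -> str:
    keys = sorted(probs)
    p = np.array([probs[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=p / p.sum()))]


def _generate_subject_day(
    config: GeneratorConfig,
    rng: np.random.Generator,
    sid: str,
    day: str,
    archetype: str,
    household_size: int,
    visits_out: list[dict],
    encounters_out: list[dict],
) -> None:
    alpha = np.asarray(config.archetype_weights[archetype], dtype=float)
    w = rng.dirichlet(alpha)

    presence = np.zeros(len(SETTINGS), dtype=bool)
    for j, s in enumerate(SETTINGS):
        p = config.presence_prob[day][s]
        presence[j] = rng.random() < p
    presence[SETTINGS.index("home")] = True
    presence[SETTINGS.index(archetype)] = True

    w = np.where(presence, w, 0.0)
    w = w / w.sum()

    total_pch = float(
        np.exp(rng.normal(np.log(config.total_pch_median), config.total_pch_sigma))
    )

    # Stay durations; rescale if the day would exceed 24 h.
    durations = np.zeros(len(SETTINGS))
    for j, s in enumerate(SETTINGS):
        med, sig = config.duration_params[s]
        durations[j] = np.exp(rng.normal(np.log(med), sig)) if presence[j] else 0.0
    total_d = durations.sum()
    if total_d > 24.0:
        durations *= 24.0 / total_d

    visit_counter = 0
    for j, s in enumerate(SETTINGS):
        if not presence[j]:
            continue
        d = durations[j]
        target = w[j] * total_pch / d
        n_setting = int(np.floor(target))
        if rng.random() < target - n_setting:  # unbiased stochastic rounding
            n_setting += 1

        a, b = config.headcount_params[s]
        ratio = rng.beta(a, b)
        n_reach = int(np.rint(ratio * n_setting))
        n_reach = min(n_reach, n_setting)

        if rng.random() < config.inconsistency_rate:
            # self-inconsistent headcounts: more in reach than in setting
            n_reach = n_setting + int(rng.integers(1, 3))

        # A setting's stay occasionally spans two diary pages.
        if rng.random() < config.visit_split_prob and d > 0.2:
            frac = rng.uniform(0.25, 0.75)
            parts = [d * frac, d * (1.0 - frac)]
        else:
            parts = [d]

        for part in parts:
            visit_counter += 1
            vid = f"v{visit_counter}"
            part = round(float(part), 6)
            visits_out.append(
                {
                    "subject_id": sid,
                    "day": day,
                    "tool": "base",
                    "visit_id": vid,
                    "setting": s,
                    "duration_h": part,
                    "n_reach": n_reach,
                    "n_setting": n_setting,
                }
            )
            _generate_encounters(
                config, rng, sid, day, vid, s, part, n_reach, encounters_out
            )


def _generate_encounters(
    config: GeneratorConfig,
    rng: np.random.Generator,
    sid: str,
    day: str,
    vid: str,
    setting: str,
    duration: float,
    n_reach: int,
    encounters_out: list[dict],
) -> None:
    if n_reach <= 0 or duration <= 0:
        return
    n_contacts = int(rng.binomial(n_reach, config.talk_prob))
    fa, fb = config.interaction_frac
    for c in range(n_contacts):
        total = float(rng.beta(fa, fb)) * duration
        if total <= 1e-6:
            continue
        touch = bool(rng.random() < (0.6 if setting == "home" else 0.2))
        if rng.random() < config.repeat_prob and total > 0.02:
            # repeated encounter with the same contact, split in two rows
            u = rng.uniform(0.3, 0.7)
            pieces = [total * u, total * (1.0 - u)]
        else:
            pieces = [total]
        for k, piece in enumerate(pieces):
            piece = min(round(piece, 6), duration)  # never outlast the visit
            if piece <= 0:
                continue
            encounters_out.append(
                {
                    "subject_id": sid,
                    "day": day,
                    "tool": "base",
                    "visit_id": vid,
                    "contact_id": f"{vid}c{c + 1}" + ("" if len(pieces) == 1 else f"r{k + 1}"),
                    "duration_h": piece,
                    "touch": touch,
                }
            )


def _thin_view(
    base: DiaryDataset,
    tool: str,
    bias: Mapping[str, float],
    rng: np.random.Generator,
) -> DiaryDataset:
    seed = int(rng.integers(0, 2**31 - 1))
    view = apply_tool_bias(base, bias, seed=seed, keep_min_one=True)
    visits = view.visits.copy()
    visits["tool"] = tool
    enc = view.encounters.copy()
    enc["tool"] = tool
    return DiaryDataset(subjects=base.subjects, visits=visits, encounters=enc)
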