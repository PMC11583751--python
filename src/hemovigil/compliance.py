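"""Standard-7 documentation compliance scoring for transfusion episodes.

A transfusion episode must document, besides consent, compatibility and
completion, at least one observation of each of the four vital-sign
categories (temperature, pulse, blood pressure, respiratory rate) in each
of four scheduled intervals:

* **baseline** — from one hour before initiation up to 5 minutes after;
* **15-minute** — 15 minutes after initiation, grace ± 5 minutes;
* **hourly** — each whole hour of the transfusion, grace ± 20 minutes,
  anchored either at the start or at the 15-minute observation, required
  only while the transfusion is still running (up to three subintervals);
* **post** — within one hour of the documented completion.

All interval bounds are closed.  When no completion record exists the post
measure is not assessable, and which hourly subintervals are required is
decided by the configured open-episode policy.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Iterable, Literal, Sequence

from pydantic import BaseModel, Field, model_validator

from .records import (
    Category,
    HOURLY_NOT_REQUIRED,
    HOURLY_REQUIRED_FAIL,
    HOURLY_REQUIRED_PASS,
    POST_FAIL,
    POST_NOT_ASSESSABLE,
    POST_PASS,
)

Window = tuple[datetime, datetime]  # closed interval [lo, hi]

ASSUME_MAX = "ASSUME_MAX"
CENSOR = "CENSOR"


class WindowPolicy(BaseModel):
    """All schedule parameters, in minutes.

    Defaults encode the monitored hospital network's schedule; other sites
    can override any of them.  ``open_episode_policy`` decides how episodes
    with no completion record are scored on the hourly measure:
    ``ASSUME_MAX`` requires every subinterval up to the maximum (a missing
    completion never excuses missing observations), ``CENSOR`` requires a
    subinterval only when later documentation proves the transfusion was
    still running.
    """

    model_config = {"frozen": True}

    baseline_before_min: int = Field(default=60, gt=0)
    baseline_after_min: int = Field(default=5, gt=0)
    t15_nominal_min: int = Field(default=15, gt=0)
    t15_grace_min: int = Field(default=5, gt=0)
    hourly_grace_min: int = Field(default=20, gt=0)
    hourly_max_subintervals: int = Field(default=3, ge=1)
    post_window_min: int = Field(default=60, gt=0)
    consent_lookback_min: int = Field(default=1440, gt=0)
    open_episode_policy: Literal["ASSUME_MAX", "CENSOR"] = ASSUME_MAX

    @model_validator(mode="after")
    def _grace_inside_nominal(self) -> "WindowPolicy":
        if self.t15_grace_min >= self.t15_nominal_min:
            raise ValueError("t15_grace_min must be smaller than t15_nominal_min")
        return self

    def assessment_horizon_min(self) -> int:
        """Attachment horizon after start for episodes with no completion."""
        return 60 * self.hourly_max_subintervals + self.post_window_min


@dataclass(frozen=True)
class ComplianceResult:
    """Per-episode pass/fail flags for every Standard-7 measure."""

    episode_id: str
    consent_documented: bool
    compatibility_documented: bool
    completion_documented: bool
    baseline_pass: bool
    min15_pass: bool
    hourly_pass: bool
    hourly_detail: tuple[tuple[int, str], ...]  # (subinterval, status)
    post_pass: str  # PASS | FAIL | NOT_ASSESSABLE
    ambiguity_flag: bool

    def hourly_status(self, k: int) -> str:
        return dict(self.hourly_detail)[k]


def _minutes(m: int) -> timedelta:
    return timedelta(minutes=m)


def min15_anchor(episode, policy: WindowPolicy) -> datetime | None:
    """Earliest attributed observation inside the 15-minute window, if any.

    This observation doubles as the alternative anchor for the hourly
    subintervals.
    """
    start = episode.start_time
    lo = start + _minutes(policy.t15_nominal_min - policy.t15_grace_min)
    hi = start + _minutes(policy.t15_nominal_min + policy.t15_grace_min)
    times = [t for (_, t, _) in episode.observations if lo <= t <= hi]
    return min(times) if times else None


def interval_windows(episode, policy: WindowPolicy) -> dict[str, list[Window]]:
    """Closed time windows for every scheduled interval of an episode.

    Hourly subinterval *k* is the union of windows around ``start + k h``
    and, when a 15-minute observation exists, around ``t15 + k h``.
    The ``POST`` entry is present only when the completion time is known.
    """
    start = episode.start_time
    windows: dict[str, list[Window]] = {
        "BASELINE": [
            (start - _minutes(policy.baseline_before_min), start + _minutes(policy.baseline_after_min))
        ],
        "MIN15": [
            (
                start + _minutes(policy.t15_nominal_min - policy.t15_grace_min),
                start + _minutes(policy.t15_nominal_min + policy.t15_grace_min),
            )
        ],
    }
    t15 = min15_anchor(episode, policy)
    g = policy.hourly_grace_min
    for k in range(1, policy.hourly_max_subintervals + 1):
        ws = [(start + _minutes(60 * k - g), start + _minutes(60 * k + g))]
        if t15 is not None:
            ws.append((t15 + _minutes(60 * k - g), t15 + _minutes(60 * k + g)))
        windows[f"HOURLY_{k}"] = ws
    if episode.end_time is not None:
        windows["POST"] = [(episode.end_time, episode.end_time + _minutes(policy.post_window_min))]
    return windows


def required_hourly_subintervals(episode, policy: WindowPolicy) -> set[int]:
    """Which hourly subintervals the episode must document.

    With a known end, hour *k* is required iff the transfusion was still
    running past ``start + k`` hours.  With no end, ``ASSUME_MAX`` requires
    all subintervals; ``CENSOR`` requires hour *k* only when the window
    closes no later than the last attributed event (i.e. documentation
    proves the episode was still in progress).
    """
    start = episode.start_time
    ks = range(1, policy.hourly_max_subintervals + 1)
    if episode.end_time is not None:
        return {k for k in ks if episode.end_time > start + _minutes(60 * k)}
    if policy.open_episode_policy == ASSUME_MAX:
        return set(ks)
    times = [t for (_, t, _) in episode.observations]
    times.append(start)
    last = max(times)
    g = policy.hourly_grace_min
    return {k for k in ks if start + _minutes(60 * k + g) <= last}


def categories_present(
    observations: Iterable, windows: Sequence[Window]
) -> set[Category]:
    """Vital-sign categories with at least one observation in the window set.

    ``observations`` are (category, timestamp, record) triples; bounds are
    closed on both ends.
    """
    present: set[Category] = set()
    for obs in observations:
        cat, t = obs[0], obs[1]
        if any(lo <= t <= hi for lo, hi in windows):
            present.add(Category(cat))
    return present


ALL_CATEGORIES = frozenset(Category)


def evaluate_episode(episode, policy: WindowPolicy | None = None) -> ComplianceResult:
    """Score one reconstructed episode against every documentation measure.

    An interval passes iff all four categories are present in its window
    set.  The post measure is ``NOT_ASSESSABLE`` exactly when no completion
    record was matched.
    """
    policy = policy or WindowPolicy()
    windows = interval_windows(episode, policy)
    required = required_hourly_subintervals(episode, policy)
    obs = episode.observations

    def interval_pass(name: str) -> bool:
        return categories_present(obs, windows[name]) == ALL_CATEGORIES

    detail = []
    for k in range(1, policy.hourly_max_subintervals + 1):
        if k not in required:
            detail.append((k, HOURLY_NOT_REQUIRED))
        elif interval_pass(f"HOURLY_{k}"):
            detail.append((k, HOURLY_REQUIRED_PASS))
        else:
            detail.append((k, HOURLY_REQUIRED_FAIL))

    completion = episode.complete is not None
    if not completion:
        post = POST_NOT_ASSESSABLE
    else:
        post = POST_PASS if interval_pass("POST") else POST_FAIL

    return ComplianceResult(
        episode_id=episode.episode_id,
        consent_documented=episode.consent_event is not None,
        compatibility_documented=episode.compatibility_event is not None,
        completion_documented=completion,
        baseline_pass=interval_pass("BASELINE"),
        min15_pass=interval_pass("MIN15"),
        hourly_pass=all(status != HOURLY_REQUIRED_FAIL for _, status in detail),
        hourly_detail=tuple(detail),
        post_pass=post,
        ambiguity_flag=episode.ambiguity_flag,
    )
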