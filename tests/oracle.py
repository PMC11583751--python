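"""Brute-force compliance evaluator, independent of hemovigil.compliance.

Windows are re-derived here with explicit minute arithmetic and every
(observation x window) pair is checked by nested loops.  This is the
reference against which the package evaluator is validated; it must stay
structurally independent of the implementation it checks.
"""

from __future__ import annotations

from datetime import timedelta


def _m(minutes: int) -> timedelta:
    return timedelta(minutes=minutes)


def brute_force_evaluate(episode, policy) -> dict:
    """Evaluate every Standard-7 measure by exhaustive containment checks."""
    start = episode.start_time
    end = episode.end_time
    obs = [(str(cat), t) for (cat, t, _rec) in episode.observations]
    all_cats = {"PULSE", "RESP_RATE", "TEMPERATURE", "BLOOD_PRESSURE"}

    def cats_in(windows):
        found = set()
        for cat, t in obs:
            for lo, hi in windows:
                if lo <= t <= hi:
                    found.add(cat)
        return found

    baseline_w = [(start - _m(policy.baseline_before_min), start + _m(policy.baseline_after_min))]
    min15_w = [
        (
            start + _m(policy.t15_nominal_min - policy.t15_grace_min),
            start + _m(policy.t15_nominal_min + policy.t15_grace_min),
        )
    ]

    # earliest observation (any category) inside the 15-minute window
    t15 = None
    for _cat, t in obs:
        if min15_w[0][0] <= t <= min15_w[0][1]:
            if t15 is None or t < t15:
                t15 = t

    g = policy.hourly_grace_min
    hourly_w = {}
    for k in range(1, policy.hourly_max_subintervals + 1):
        ws = [(start + _m(60 * k - g), start + _m(60 * k + g))]
        if t15 is not None:
            ws.append((t15 + _m(60 * k - g), t15 + _m(60 * k + g)))
        hourly_w[k] = ws

    # which hourly subintervals are required
    if end is not None:
        required = {k for k in hourly_w if end > start + _m(60 * k)}
    elif policy.open_episode_policy == "ASSUME_MAX":
        required = set(hourly_w)
    else:  # CENSOR
        last = start
        for _cat, t in obs:
            if t > last:
                last = t
        required = {k for k in hourly_w if start + _m(60 * k + g) <= last}

    detail = {}
    for k in hourly_w:
        if k not in required:
            detail[k] = "NOT_REQUIRED"
        elif cats_in(hourly_w[k]) == all_cats:
            detail[k] = "REQUIRED_PASS"
        else:
            detail[k] = "REQUIRED_FAIL"

    if episode.complete is None:
        post = "NOT_ASSESSABLE"
    else:
        post_w = [(end, end + _m(policy.post_window_min))]
        post = "PASS" if cats_in(post_w) == all_cats else "FAIL"

    return {
        "consent_documented": episode.consent_event is not None,
        "compatibility_documented": episode.compatibility_event is not None,
        "completion_documented": episode.complete is not None,
        "baseline_pass": cats_in(baseline_w) == all_cats,
        "min15_pass": cats_in(min15_w) == all_cats,
        "hourly_detail": detail,
        "hourly_pass": all(v != "REQUIRED_FAIL" for v in detail.values()),
        "post_pass": post,
    }


def assert_agrees(result, oracle: dict) -> None:
    """Field-by-field comparison of a ComplianceResult against the oracle."""
    assert result.consent_documented == oracle["consent_documented"]
    assert result.compatibility_documented == oracle["compatibility_documented"]
    assert result.completion_documented == oracle["completion_documented"]
    assert result.baseline_pass == oracle["baseline_pass"]
    assert result.min15_pass == oracle["min15_pass"]
    assert dict(result.hourly_detail) == oracle["hourly_detail"]
    assert result.hourly_pass == oracle["hourly_pass"]
    assert result.post_pass == oracle["post_pass"]
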