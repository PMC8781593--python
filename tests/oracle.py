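"""Independent brute-force oracles used only by the tests.

These deliberately re-derive day classification and episode boundaries with
a different algorithm (set logic plus a quadratic jump-and-rescan over the
day sequence) so they can cross-check the production single-pass engine.
"""

from __future__ import annotations

A_LIST = {"fever", "wheezing", "wet_cough", "dx_pneumonia", "dx_otitis_media"}
B_LIST = {"dry_cough", "chills", "sore_throat", "runny_or_blocked_nose",
          "increased_need_to_sleep", "loss_of_appetite", "increased_attachment"}

# class symbols, ordered so that >= "single_b" means symptomatic
MISSING, FREE, SINGLE_B, B_PAIR, A = "missing", "free", "single_b", "b_pair", "a_day"
_ORDER = {MISSING: 0, FREE: 1, SINGLE_B: 2, B_PAIR: 3, A: 4}


def oracle_classify(present: set[str] | None) -> str:
    """Classify one day from the set of present symptom/diagnosis names.

    ``None`` means no diary entry.
    """
    if present is None:
        return MISSING
    if present & A_LIST:
        return A
    n_b = len(present & B_LIST)
    if n_b >= 2:
        return B_PAIR
    if n_b == 1:
        return SINGLE_B
    return FREE


def _symptomatic(c: str) -> bool:
    return _ORDER[c] >= _ORDER[SINGLE_B]


def _counter_days(classes: list[str], i: int, j: int, missing_rule: str) -> int:
    """Days strictly between i and j that tick the 3-day recovery counter."""
    n = 0
    for k in range(i + 1, j):
        c = classes[k]
        if c == FREE or (c == MISSING and missing_rule == "free"):
            n += 1
    return n


def oracle_segment(classes: list[str], missing_rule: str = "free",
                   ) -> tuple[list[tuple], list[int]]:
    """Quadratic re-scan segmentation.

    Returns episodes as (start, last_symptom_day, trigger, censored,
    n_symptom_days) in day offsets, and the list of orphan single-B days.
    """
    n = len(classes)
    episodes: list[tuple] = []
    covered: set[int] = set()
    d = 0
    while d < n:
        if d not in covered and _ORDER[classes[d]] >= _ORDER[B_PAIR]:
            start = last = d
            while True:
                nxt = None
                for j in range(last + 1, n):
                    if _symptomatic(classes[j]):
                        nxt = j
                        break
                if nxt is None or _counter_days(classes, last, nxt, missing_rule) >= 3:
                    break
                last = nxt
            censored = _counter_days(classes, last, n, missing_rule) < 3
            trigger = "A_symptom" if classes[start] == A else "B_pair"
            n_sym = sum(_symptomatic(classes[k]) for k in range(start, last + 1))
            episodes.append((start, last, trigger, censored, n_sym))
            covered.update(range(start, last + 1))
            d = last + 1
        else:
            d += 1
    orphans = [k for k in range(n) if classes[k] == SINGLE_B and k not in covered]
    return episodes, orphans
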