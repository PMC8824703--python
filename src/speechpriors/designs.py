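"""Seedable trial schedules for the four experiments.

Design tables are ordered pandas DataFrames, one row per trial, with columns
``experiment, condition, phase, block, position, kind, stimulus_id`` (plus
``sentence_a, sentence_b`` where stimuli are two-sentence mixtures).  Every
table is exactly reproducible from (experiment, seed, counterbalance index).

Experiments:

* 1a/1b — "one-shot" modulation design: 90 discrimination trials
  (45 intelligible, 45 unintelligible) before and after a single exposure
  pass over the 45 clear templates; 1b adds a primed/control group split.
* 2 — two acoustic conditions (band count x SNR), each 8 cycles of
  10 pre-exposure trials, 5 clear templates, and the same 10 trials
  re-shuffled post-exposure; no sentence repeats anywhere in the session.
* 3 — naive listening: 6 blocks of 15 sine-vocoded stimuli plus 3 'scratchy'
  targets, pseudo-randomised with no more than two of a kind in a row,
  followed by a 46-word recognition-memory list.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: bounded retries for pseudo-randomisation constraints
MAX_RETRIES = 10_000

# common monosyllabic nouns of the kind used as sentence keywords; the
# memory task draws its hidden words and length-matched foils from this pool
WORD_POOL = (
    "clock table spoon bread house train shoes grass cloth stairs "
    "sheep plate brush field straw glass chair knife river stone "
    "dress horse cream fence wheel torch crowd sweet plant stick "
    "truck scarf broom drain flask grape shelf cliff stool crane"
).split()

# irregularly spelled low-frequency words of the reading-test kind, plus
# spelling-matched foils never presented
NART_WORDS = ("ache", "debt", "psalm", "thyme", "gauge")
NART_FOILS = ("gnome", "knead", "wrath", "heir", "czar")


def _shuffled(rng: np.random.Generator, items) -> list:
    items = list(items)
    rng.shuffle(items)
    return items


def build_exp1_design(seed: int, experiment: str = "1a") -> pd.DataFrame:
    """One-shot test–train–retest schedule of experiments 1a/1b.

    90 pre-exposure trials (45 intelligible, 45 unintelligible), one exposure
    pass over the 45 templates, then the same 90 stimuli re-shuffled
    post-exposure.
    """
    rng = np.random.default_rng(seed)
    intel = [f"sws_i{i:02d}" for i in range(1, 46)]
    unint = [f"sws_u{i:02d}" for i in range(1, 46)]
    pre = _shuffled(rng, intel + unint)
    post = _shuffled(rng, intel + unint)
    rows = []
    for pos, sid in enumerate(pre, 1):
        rows.append((experiment, "sws", "pre", 1, pos,
                     "intelligible" if sid in set(intel) else "unintelligible", sid))
    for pos, sid in enumerate(_shuffled(rng, intel), 1):
        rows.append((experiment, "sws", "exposure", 1, pos, "template",
                     sid.replace("sws_i", "template_")))
    for pos, sid in enumerate(post, 1):
        rows.append((experiment, "sws", "post", 1, pos,
                     "intelligible" if sid in set(intel) else "unintelligible", sid))
    return pd.DataFrame(
        rows, columns=["experiment", "condition", "phase", "block", "position",
                       "kind", "stimulus_id"])


def build_prime_assignment(n: int, seed: int) -> np.ndarray:
    """Equal split of ``n`` participants into 'primed' and 'control'."""
    if n % 2 != 0:
        raise ValueError("n must be even for an equal primed/control split")
    rng = np.random.default_rng(seed)
    labels = np.array(["primed"] * (n // 2) + ["control"] * (n // 2))
    rng.shuffle(labels)
    return labels


# the common condition every group receives, plus the five alternates used
# to scope difficulty (band count, SNR dB)
EXP2_COMMON = (8, 6.0)
EXP2_ALTERNATES = ((16, 6.0), (8, 0.0), (16, 0.0), (8, -6.0), (16, -6.0))


def _condition_label(n_bands: int, snr_db: float) -> str:
    sign = "+" if snr_db >= 0 else ""
    return f"{n_bands}band{sign}{snr_db:g}dB"


def build_exp2_session(counterbalance_index: int, seed: int,
                       sentence_pool_size: int = 320) -> pd.DataFrame:
    """Full experiment-2 session for one participant slot.

    ``counterbalance_index`` selects the alternate acoustic condition and the
    condition order (10 distinct schemes); the sentence-set assignment is a
    seeded draw from a pool large enough that no sentence repeats anywhere in
    the session.  Each condition runs 8 cycles of (10 pre | 5 templates |
    10 post); the post list is a re-shuffle of that cycle's pre list.
    """
    # 80 stimuli/condition x 2 sentences each = 320 sentences minimum
    needed = 2 * 2 * 8 * 10
    if sentence_pool_size < needed:
        raise ValueError(
            f"sentence pool of {sentence_pool_size} cannot satisfy the "
            f"no-repetition constraint (needs >= {needed})")
    rng = np.random.default_rng(seed)
    alt = EXP2_ALTERNATES[counterbalance_index % len(EXP2_ALTERNATES)]
    conditions = [EXP2_COMMON, alt]
    if (counterbalance_index // len(EXP2_ALTERNATES)) % 2 == 1:
        conditions = conditions[::-1]

    sentences = _shuffled(rng, [f"s{i:04d}" for i in range(1, sentence_pool_size + 1)])
    draw = iter(sentences)
    rows = []
    for nb, snr in conditions:
        label = _condition_label(nb, snr)
        for cycle in range(1, 9):
            stims = []
            for j in range(5):
                a, b = next(draw), next(draw)
                stims.append((f"{label}_c{cycle}_i{j + 1}", "intelligible", a, b))
            for j in range(5):
                a, b = next(draw), next(draw)
                stims.append((f"{label}_c{cycle}_u{j + 1}", "unintelligible", a, b))
            pre = _shuffled(rng, stims)
            post = _shuffled(rng, stims)
            for _ in range(MAX_RETRIES):
                if post != pre:
                    break
                post = _shuffled(rng, stims)
            for pos, (sid, kind, a, b) in enumerate(pre, 1):
                rows.append(("2", label, "pre", cycle, pos, kind, sid, a, b))
            templates = [s for s in stims if s[1] == "intelligible"]
            for pos, (sid, kind, a, b) in enumerate(templates, 1):
                rows.append(("2", label, "exposure", cycle, pos, "template",
                             sid.replace("_i", "_t"), a, ""))
            for pos, (sid, kind, a, b) in enumerate(post, 1):
                rows.append(("2", label, "post", cycle, pos, kind, sid, a, b))
    return pd.DataFrame(
        rows, columns=["experiment", "condition", "phase", "block", "position",
                       "kind", "stimulus_id", "sentence_a", "sentence_b"])


def _sequence_with_max_run(rng: np.random.Generator, kinds: list[str],
                           prev_tail: list[str], max_run: int = 2) -> list[str]:
    """Seeded rejection sampling of a shuffle whose concatenation with
    ``prev_tail`` never exceeds ``max_run`` consecutive identical kinds."""
    for _ in range(MAX_RETRIES):
        seq = _shuffled(rng, kinds)
        full = prev_tail + seq
        run, ok = 1, True
        for i in range(1, len(full)):
            run = run + 1 if full[i] == full[i - 1] else 1
            if run > max_run:
                ok = False
                break
        if ok:
            return seq
    raise RuntimeError(
        f"run-length constraint unsatisfiable after {MAX_RETRIES} retries")


def build_exp3_design(seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Naive-listening schedule and recognition-memory list of experiment 3.

    Returns ``(trials, memory_list)``.  Trials: an 8-trial familiarization
    preamble (3 targets, 5 unintelligible), then 6 blocks of 18 sounds
    (15 sine-vocoded stimuli + 3 targets) with 45 intelligible and 45
    unintelligible overall and no more than two of a kind consecutively.
    Memory list: 18 hidden words (3 per block), 18 matched foils, 5 reading-
    test words and 5 spelling-matched foils, shuffled.
    """
    rng = np.random.default_rng(seed)
    # per-block intelligible counts: 45 over 6 blocks of 15
    intel_counts = _shuffled(rng, [8, 8, 8, 7, 7, 7])

    rows = []
    fam = _sequence_with_max_run(
        rng, ["target"] * 3 + ["unintelligible"] * 5, prev_tail=[])
    counters = {"intelligible": 0, "unintelligible": 0, "target": 0}
    for pos, kind in enumerate(fam, 1):
        counters[kind] += 1
        rows.append(("3", "16band+6dB", "familiarization", 0, pos, kind,
                     f"fam_{kind[0]}{counters[kind]}"))
    tail: list[str] = []
    counters = {"intelligible": 0, "unintelligible": 0, "target": 0}
    for block in range(1, 7):
        kinds = (["intelligible"] * intel_counts[block - 1]
                 + ["unintelligible"] * (15 - intel_counts[block - 1])
                 + ["target"] * 3)
        seq = _sequence_with_max_run(rng, kinds, prev_tail=tail)
        for pos, kind in enumerate(seq, 1):
            counters[kind] += 1
            sid = f"svs_{kind[0]}{counters[kind]:02d}" if kind != "target" \
                else f"target_{counters[kind]:02d}"
            rows.append(("3", "16band+6dB", "naive", block, pos, kind, sid))
        run = 1
        tail = [seq[-1]]
        for k in reversed(seq[:-1]):
            if k == tail[0]:
                tail.insert(0, k)
            else:
                break
        tail = tail[-2:]
    trials = pd.DataFrame(
        rows, columns=["experiment", "condition", "phase", "block", "position",
                       "kind", "stimulus_id"])

    words = _shuffled(rng, WORD_POOL)
    hidden, foils = words[:18], words[18:36]
    mem_rows = [
        {"word": w, "category": "hidden", "block_of_occurrence": 1 + i // 3}
        for i, w in enumerate(hidden)
    ]
    mem_rows += [{"word": w, "category": "matched_foil", "block_of_occurrence": None}
                 for w in foils]
    mem_rows += [{"word": w, "category": "nart", "block_of_occurrence": None}
                 for w in NART_WORDS]
    mem_rows += [{"word": w, "category": "nart_foil", "block_of_occurrence": None}
                 for w in NART_FOILS]
    rng.shuffle(mem_rows)
    memory = pd.DataFrame(mem_rows)
    return trials, memory
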