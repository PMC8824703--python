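"""Latent-trait generative model of the participant cohort.

A single standard-normal latent trait — hallucination-proneness — drives all
individual differences the analyses probe:

* questionnaire scores are monotone noisy transforms of the trait
  (graded-threshold items for the 5-item auditory hallucination scale;
  over-dispersed counts for the anomalous-perception and delusion
  frequency totals);
* discrimination follows the equal-variance SDT response model, with
  pre- and post-exposure d' carrying independent measurement noise around
  trait-determined means, so under the modulation coupling gamma_mod the
  trait–(post-pre) correlation is gamma_mod / sqrt(gamma_mod^2 + 2*noise_sd^2);
* spontaneous recognition of hidden speech under naive listening is a
  logistic function of the trait (and optionally of reading-test score),
  with a trait-dependent truncated-geometric recognition block;
* recognition memory for hidden words depends on how early speech was
  recognised, while lure endorsement and reading-test-word memory are
  trait-independent.

Three named scenarios switch the couplings: ``null`` (no trait coupling
anywhere), ``modulation`` (trait scales the exposure benefit) and ``naive``
(trait drives spontaneous recognition and hence hidden-word memory).

All randomness flows from one root seed through named ``SeedSequence``
spawns (cohort, discrimination, naive listening, memory), so each stage is
reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr

from .sdt import sdt_outcome_arrays


@dataclass(frozen=True)
class CohortParams:
    """Parameters of the generative cohort model (defaults = null scenario)."""

    n: int = 60
    mu_dprime_pre: float = 1.5
    exposure_gain: float = 0.7
    gamma_pre: float = 0.0        # trait -> baseline d' (z-units per trait SD)
    gamma_mod: float = 0.0        # trait -> exposure benefit (z-units per trait SD)
    gamma_naive: float = 0.0      # trait -> spontaneous recognition (log-odds per SD)
    beta_nart: float = 0.0        # reading score -> recognition (log-odds per point)
    mu_criterion: float = 0.2
    sd_criterion: float = 0.4
    noise_sd: float = 0.3
    q_encode: float = 0.6         # P(Remember) for hidden words heard post-recognition
    fa_lure: float = 0.15         # P(endorse) for never-presented foils
    seed: int = 0
    # marginals of the auxiliary measures
    alpha_recognize: float = 0.5  # recognition log-odds intercept (~62% recognisers)
    lshs_thresholds: tuple[float, float, float] = (-0.2, 1.0, 2.2)
    lshs_item_noise: float = 1.0
    caps_mu: float = 12.0
    pdi_mu: float = 8.0
    count_trait_slope: float = 0.5
    count_dispersion: float = 2.0
    nart_mean: float = 35.0
    nart_sd: float = 5.0
    rho_nart: float = 0.0         # optional trait–reading-score correlation
    block_p0: float = -0.85       # logit of geometric success at trait 0
    block_slope: float = 0.25     # earlier recognition for higher trait
    r_base: float = 0.05          # Remember base rate without decoding
    k_rate: float = 0.2           # Know rate for non-remembered presented words
    q_nart: float = 0.4           # Remember rate for reading-test words

    def __post_init__(self) -> None:
        bad = []
        if self.n < 2:
            bad.append("n (must be >= 2)")
        for name in ("sd_criterion", "noise_sd", "nart_sd", "lshs_item_noise",
                     "count_dispersion"):
            if getattr(self, name) < 0:
                bad.append(f"{name} (must be >= 0)")
        for name in ("q_encode", "fa_lure", "r_base", "k_rate", "q_nart"):
            if not 0 <= getattr(self, name) <= 1:
                bad.append(f"{name} (must be a probability)")
        if not -1 <= self.rho_nart <= 1:
            bad.append("rho_nart (must be a correlation)")
        if bad:
            raise ValueError("invalid CohortParams: " + ", ".join(bad))


SCENARIOS = {
    "null": {},
    "modulation": {"gamma_mod": 0.3},
    "naive": {"gamma_naive": 1.0, "beta_nart": 0.1, "rho_nart": 0.0},
}


def scenario_params(name: str, **overrides) -> CohortParams:
    """Named scenario with optional field overrides."""
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    return replace(CohortParams(), **(SCENARIOS[name] | overrides))


def load_scenario(path) -> CohortParams:
    """Scenario from a YAML file: ``scenario: <name>`` plus field overrides.

    Example::

        scenario: naive
        n: 134
        seed: 3
        q_encode: 0.5
    """
    import yaml

    with open(path) as fh:
        spec = yaml.safe_load(fh) or {}
    if not isinstance(spec, dict) or "scenario" not in spec:
        raise ValueError("scenario file must be a mapping with a 'scenario' key")
    name = spec.pop("scenario")
    known = {f.name for f in fields(CohortParams)}
    unknown = set(spec) - known
    if unknown:
        raise ValueError(f"unknown parameter overrides: {sorted(unknown)}")
    return scenario_params(name, **spec)


@dataclass(frozen=True)
class Observer:
    """One simulated participant."""

    id: int
    trait_h: float
    lshs_a: int
    caps_freq: int
    pdi_freq: int
    nart: int
    dprime_pre: float
    dprime_post: float
    criterion: float
    recognized: bool | None = None
    recognition_block: int | None = None


def _streams(params: CohortParams) -> dict[str, np.random.Generator]:
    names = ("cohort", "discrimination", "naive", "memory")
    seqs = np.random.SeedSequence(params.seed).spawn(len(names))
    return {name: np.random.default_rng(s) for name, s in zip(names, seqs)}


def sample_cohort(params: CohortParams) -> list[Observer]:
    """Draw the cohort from the latent-trait model; reproducible per seed."""
    rng = _streams(params)["cohort"]
    n = params.n
    trait = rng.standard_normal(n)

    # 5 graded items, each scored 1-4 by thresholding trait + item noise
    taus = np.asarray(params.lshs_thresholds)
    item_lat = trait[:, None] + params.lshs_item_noise * rng.standard_normal((n, 5))
    lshs = 5 + (item_lat[:, :, None] > taus).sum(axis=(1, 2))

    def nb_counts(mu0: float) -> np.ndarray:
        mu = mu0 * np.exp(params.count_trait_slope * trait)
        r = params.count_dispersion
        return rng.negative_binomial(r, r / (r + mu))

    caps = nb_counts(params.caps_mu)
    pdi = nb_counts(params.pdi_mu)

    nart_z = (params.rho_nart * trait
              + np.sqrt(1 - params.rho_nart**2) * rng.standard_normal(n))
    nart = np.clip(np.round(params.nart_mean + params.nart_sd * nart_z), 10, 50)

    base = params.mu_dprime_pre + params.gamma_pre * trait
    d_pre = base + params.noise_sd * rng.standard_normal(n)
    d_post = (base + params.exposure_gain + params.gamma_mod * trait
              + params.noise_sd * rng.standard_normal(n))
    crit = params.mu_criterion + params.sd_criterion * rng.standard_normal(n)

    return [
        Observer(id=i + 1, trait_h=float(trait[i]), lshs_a=int(lshs[i]),
                 caps_freq=int(caps[i]), pdi_freq=int(pdi[i]), nart=int(nart[i]),
                 dprime_pre=float(d_pre[i]), dprime_post=float(d_post[i]),
                 criterion=float(crit[i]))
        for i in range(n)
    ]


def cohort_table(cohort: list[Observer]) -> pd.DataFrame:
    """Cohort as a one-row-per-observer DataFrame (keyed by ``participant``)."""
    return pd.DataFrame([vars(o) for o in cohort]).rename(columns={"id": "participant"})


# ---------------------------------------------------------------------------
# trial-level response simulation (equal-variance SDT observer)


def yes_probability(d_prime: float, criterion: float, kind: str) -> float:
    """P("contains speech") for one trial under the equal-variance model."""
    sign = 1.0 if kind == "intelligible" else -1.0
    return float(ndtr(sign * d_prime / 2.0 - criterion))


def simulate_discrimination(obs: Observer, design: pd.DataFrame,
                            rng: np.random.Generator | None = None,
                            seed: int | None = None) -> pd.DataFrame:
    """Per-trial yes/no responses for the pre/post discrimination phases.

    P(yes | intelligible) = Phi(d'/2 - c), P(yes | unintelligible) =
    Phi(-d'/2 - c), with the phase-specific d'.
    """
    if rng is None:
        rng = np.random.default_rng(obs.id if seed is None else seed)
    disc = design[design["phase"].isin(["pre", "post"])]
    if disc.empty:
        raise ValueError("design contains no pre/post discrimination trials")
    d = np.where(disc["phase"] == "pre", obs.dprime_pre, obs.dprime_post)
    sign = np.where(disc["kind"] == "intelligible", 1.0, -1.0)
    p_yes = ndtr(sign * d / 2.0 - obs.criterion)
    out = disc[["phase", "block", "position", "kind", "stimulus_id"]].copy()
    out.insert(0, "participant", obs.id)
    out["said_speech"] = rng.random(len(disc)) < p_yes
    return out.reset_index(drop=True)


def simulate_cohort_counts(cohort: list[Observer], n_signal: int, n_noise: int,
                           rng: np.random.Generator) -> pd.DataFrame:
    """Vectorised pre/post hit and false-alarm counts for a whole cohort.

    Distributionally identical to running ``simulate_discrimination`` trial by
    trial on a balanced design and tallying counts (independent Bernoulli
    trials with a common per-kind probability sum to a binomial), and is the
    fast path for replicated simulations.  Returns recovered d'/C per phase.
    """
    d_pre = np.array([o.dprime_pre for o in cohort])
    d_post = np.array([o.dprime_post for o in cohort])
    c = np.array([o.criterion for o in cohort])
    rows = {}
    for phase, d in (("pre", d_pre), ("post", d_post)):
        hits = rng.binomial(n_signal, ndtr(d / 2.0 - c))
        fas = rng.binomial(n_noise, ndtr(-d / 2.0 - c))
        dp, cc, beta = sdt_outcome_arrays(hits, n_signal, fas, n_noise)
        rows[phase] = dict(hits=hits, fas=fas, d_prime=dp, C=cc, beta=beta)
    return pd.DataFrame({
        "participant": [o.id for o in cohort],
        "lshs_a": [o.lshs_a for o in cohort],
        "caps_freq": [o.caps_freq for o in cohort],
        "pdi_freq": [o.pdi_freq for o in cohort],
        "trait_h": [o.trait_h for o in cohort],
        "d_prime_pre": rows["pre"]["d_prime"], "C_pre": rows["pre"]["C"],
        "beta_pre": rows["pre"]["beta"],
        "d_prime_post": rows["post"]["d_prime"], "C_post": rows["post"]["C"],
        "beta_post": rows["post"]["beta"],
    })


# ---------------------------------------------------------------------------
# naive listening + recognition memory


def simulate_naive_listening(obs: Observer, params: CohortParams,
                             rng: np.random.Generator | None = None
                             ) -> tuple[bool, int | None]:
    """Spontaneous recognition of hidden speech and its block.

    P(recognised) = logistic(alpha + gamma_naive*trait + beta_nart*(nart -
    mean)); recognisers get a block from a truncated geometric on 1..6 whose
    success probability increases with the trait (earlier recognition).
    """
    if rng is None:
        rng = np.random.default_rng(obs.id)
    p_rec = expit(params.alpha_recognize + params.gamma_naive * obs.trait_h
                  + params.beta_nart * (obs.nart - params.nart_mean))
    if rng.random() >= p_rec:
        return False, None
    p_geo = expit(params.block_p0 + params.block_slope * obs.trait_h)
    k = np.arange(1, 7)
    w = p_geo * (1 - p_geo) ** (k - 1)
    block = int(rng.choice(k, p=w / w.sum()))
    return True, block


def simulate_memory(obs: Observer, memory_list: pd.DataFrame,
                    params: CohortParams,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Remember/Know/New responses to the 46-word memory list.

    Hidden words from blocks at or after the recognition point are Remembered
    with probability ``q_encode``; hidden words never decoded fall back to a
    low base rate.  Foils are endorsed with probability ``fa_lure`` and
    reading-test words Remembered at ``q_nart``, both independent of the
    trait — the specificity structure the memory analysis tests.
    """
    required = {"word", "category", "block_of_occurrence"}
    if not required <= set(memory_list.columns):
        raise ValueError(f"memory list missing columns: {sorted(required - set(memory_list.columns))}")
    cats = set(memory_list["category"])
    if not {"hidden", "matched_foil", "nart", "nart_foil"} <= cats:
        raise ValueError("memory list must contain all four word categories")
    if rng is None:
        rng = np.random.default_rng(obs.id)
    if obs.recognized is None:
        raise ValueError("run simulate_naive_listening before simulate_memory")
    responses = []
    for row in memory_list.itertuples(index=False):
        u = rng.random()
        if row.category == "hidden":
            decoded = (obs.recognized
                       and row.block_of_occurrence >= obs.recognition_block)
            p_r = params.q_encode if decoded else params.r_base
        elif row.category == "nart":
            p_r = params.q_nart
        else:  # never-presented foils
            p_r = 0.3 * params.fa_lure
        if u < p_r:
            resp = "R"
        elif row.category in ("matched_foil", "nart_foil"):
            resp = "K" if u < params.fa_lure else "N"
        else:
            resp = "K" if u < p_r + params.k_rate else "N"
        responses.append(resp)
    out = memory_list.copy()
    out.insert(0, "participant", obs.id)
    out["response"] = responses
    return out


def run_naive_cohort(params: CohortParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort table with recognition outcomes, plus per-observer memory scores.

    Convenience end-to-end runner for the naive-listening study: samples the
    cohort, simulates recognition and the memory task on a fresh seeded
    memory list, and returns (cohort_df, memory_scores) where memory_scores
    has one row per observer with R-counts per word category.
    """
    from .designs import build_exp3_design

    streams = _streams(params)
    cohort = sample_cohort(params)
    _, memory_list = build_exp3_design(params.seed)
    rng_n, rng_m = streams["naive"], streams["memory"]
    enriched = []
    scores = []
    for obs in cohort:
        rec, block = simulate_naive_listening(obs, params, rng_n)
        obs = replace(obs, recognized=rec, recognition_block=block)
        enriched.append(obs)
        mem = simulate_memory(obs, memory_list, params, rng_m)
        r = mem[mem["response"] == "R"]
        endorsed = mem[mem["response"].isin(["R", "K"])]
        scores.append({
            "participant": obs.id,
            "r_hidden": int((r["category"] == "hidden").sum()),
            "lure_endorsed": int(endorsed["category"].isin(
                ["matched_foil", "nart_foil"]).sum()),
            "r_nart": int((r["category"] == "nart").sum()),
        })
    return cohort_table(enriched), pd.DataFrame(scores)
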