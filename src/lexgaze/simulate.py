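"""Synthetic cohort generator with known effect structure.

Emulates every input of the analysis pipeline so the full chain —
checklist vocabularies, feature-norm networks, the counterbalanced 24-trial
looking-while-listening design, comprehension ratings and 500 Hz gaze
streams — is testable end to end without any external data.  The gaze
generator is a four-state Markov chain whose post-latency stationary
target-vs-distractor odds encode configurable structure effects, recorded in
a :class:`SimTruth` so fitted models can be checked against the generating
coefficients.

The generator is deterministic given (config, seed): every stage draws from
a dedicated child of one seed sequence, and each trial's gaze stream has its
own substream keyed by trial index, so trial order never changes draws.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import yaml

from .gaze import GazeState, GazeTrial, SAMPLE_MS
from .network import FeatureNorms, NormsAdjacency, StructureMetrics
from .vocab import (
    EXPERIMENTAL_CATEGORIES,
    ChecklistDefinition,
    ChildVocabulary,
    DensityAssignment,
    VocabGroupAssignment,
    assign_density,
    category_proportions,
    split_vocab_groups,
)

#: The 12 experimental items and their categories.
EXPERIMENTAL_ITEMS = {
    "dog": "ANIMALS", "bird": "ANIMALS",
    "banana": "FRUIT", "apple": "FRUIT",
    "shoe": "CLOTHING", "diaper": "CLOTHING",
    "car": "VEHICLES", "airplane": "VEHICLES",
    "juice": "DRINKS", "milk": "DRINKS",
    "nose": "BODY-PARTS", "mouth": "BODY-PARTS",
}

#: Yoked same-category pairs (related trials).
RELATED_PAIRS = [
    ("dog", "bird"), ("banana", "apple"), ("shoe", "diaper"),
    ("car", "airplane"), ("juice", "milk"), ("nose", "mouth"),
]

#: Cross-category pairings (unrelated trials): FRUIT-DRINK, VEHICLES-CLOTHING,
#: BODY-PARTS-ANIMALS.
UNRELATED_PAIRS = [
    ("banana", "juice"), ("apple", "milk"),
    ("car", "shoe"), ("airplane", "diaper"),
    ("nose", "bird"), ("mouth", "dog"),
]

#: Filler categories so the checklist covers a full productive range.
FILLER_CATEGORIES = {"HOUSEHOLD": 60, "PEOPLE": 20, "ACTIONS": 80, "OTHER": 114}

COND_CODE = {"related": 0.5, "unrelated": -0.5}
GROUP_CODE = {"High": -0.5, "Low": 0.5}
DENSITY_CODE = {"High": -0.5, "Low": 0.5}

# spawn keys for the per-stage random substreams
_KEY_NORMS, _KEY_CHILDREN, _KEY_DESIGN, _KEY_RATINGS, _KEY_TRUTH, _KEY_GAZE = range(6)


@dataclass
class NormsParams:
    """Feature-norm generation: per-concept features and pair sharing."""

    idiosyncratic_perceptual: int = 2
    idiosyncratic_functional: int = 2
    p_within: float = 0.35   # P(within-category pair shares >= 2 percep/func)
    p_between: float = 0.03  # same, between categories

    def validate(self) -> None:
        for p in (self.p_within, self.p_between):
            if not 0.0 <= p <= 1.0:
                raise ValueError("sharing probabilities must be in [0, 1]")


@dataclass
class VocabParams:
    """Productive vocabulary sizes and per-child category composition.

    Sizes are log-normal truncated to the observed 10-374 word range; the
    default (mu, sigma) are calibrated numerically so the truncated
    distribution has median 61 and mean 92.1 words (its SD, ~84, then falls
    near the observed 76.3).  ``concentration`` scales the Dirichlet over
    category weights: small values make category-density rankings vary
    strongly across children; infinity makes every child's composition
    identical.
    """

    mu: float = 4.10883
    sigma: float = 1.42433
    min_words: int = 10
    max_words: int = 374
    concentration: float = 30.0


@dataclass
class GazeParams:
    """Markov gaze-stream generator.

    Post-latency stationary target:distractor odds are exp(eta) with
    eta = beta0 + beta_cond * cond_code
        + (sum_m beta[cond][m] * x_m) * (1 + gamma[cond] * group_code)
        + item intercept,
    where x_m are the cohort-standardized structure metrics, cond_code is
    +/-0.5 (related high) and group_code +/-0.5 (High vocabulary = -0.5).
    Default effect directions and magnitudes mirror the study pattern:
    lexicon-level clustering interferes in related contexts (concentrated in
    the high-vocabulary group), category density facilitates in unrelated
    contexts (concentrated in the low-vocabulary group).
    """

    beta0: float = 0.8
    beta_cond: float = 0.25
    beta: dict = field(default_factory=lambda: {
        "related": {"gcc": -0.4, "degree": 0.0, "density": -0.2},
        "unrelated": {"gcc": 0.0, "degree": 0.0, "density": 0.35},
    })
    gamma: dict = field(default_factory=lambda: {"related": -1.5, "unrelated": 1.5})
    item_intercept_sd: float = 0.3
    latency_ms: float = 500.0
    stay_prob: float = 0.97
    other_share: float = 0.3      # onscreen mass on neither interest area
    offscreen_rate: float = 0.08  # stationary offscreen probability
    fussy_trial_prob: float = 0.045
    fussy_offscreen_rate: float = 0.9
    trial_duration_ms: float = 4000.0

    def validate(self) -> None:
        if not 0.0 < self.stay_prob < 1.0:
            raise ValueError("stay_prob must be in (0, 1)")
        for p in (self.other_share, self.offscreen_rate,
                  self.fussy_trial_prob, self.fussy_offscreen_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.offscreen_rate >= 1.0 or self.fussy_offscreen_rate >= 1.0:
            raise ValueError("offscreen rates leave no onscreen mass")


@dataclass
class SimConfig:
    """Full generative configuration for one synthetic cohort."""

    seed: int = 0
    n_children: int = 79
    low_rating_prob: float = 0.048
    norms: NormsParams = field(default_factory=NormsParams)
    vocab: VocabParams = field(default_factory=VocabParams)
    gaze: GazeParams = field(default_factory=GazeParams)

    def __post_init__(self) -> None:
        if isinstance(self.norms, dict):
            self.norms = NormsParams(**self.norms)
        if isinstance(self.vocab, dict):
            self.vocab = VocabParams(**self.vocab)
        if isinstance(self.gaze, dict):
            self.gaze = GazeParams(**self.gaze)
        if self.n_children < 2:
            raise ValueError("n_children must be >= 2")
        if not 0.0 <= self.low_rating_prob <= 1.0:
            raise ValueError("low_rating_prob must be in [0, 1]")
        self.norms.validate()
        self.gaze.validate()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class SimTruth:
    """Realized generating coefficients; the oracle for recovery tests."""

    beta0: float
    beta_cond: float
    beta: dict
    gamma: dict
    item_intercepts: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _substream(seed: int, key: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(key, *extra))
    )


def make_checklist() -> ChecklistDefinition:
    """Synthetic CDI-style checklist: the six experimental categories at
    their real item counts (containing the 12 experimental items) plus
    filler categories, 400 words in total."""
    items: dict[str, str] = dict(EXPERIMENTAL_ITEMS)
    for cat, size in EXPERIMENTAL_CATEGORIES.items():
        have = sum(1 for c in items.values() if c == cat)
        for i in range(size - have):
            items[f"{cat.lower().replace('-', '_')}_{i:02d}"] = cat
    for cat, size in FILLER_CATEGORIES.items():
        for i in range(size):
            items[f"{cat.lower()}_{i:02d}"] = cat
    return ChecklistDefinition(items=items)


def gen_norms(config: SimConfig, checklist: ChecklistDefinition | None = None) -> FeatureNorms:
    """Feature norms over every checklist concept.

    Each concept gets idiosyncratic perceptual/functional features, one
    taxonomic category-membership feature shared category-wide, and one
    encyclopedic feature; each concept pair gets, with the configured
    within/between probability, a dedicated pair of shared
    perceptual+functional features, so the >= 2 shared-feature edge rule
    fires for exactly the sampled pairs.
    """
    p = config.norms
    if checklist is None:
        checklist = make_checklist()
    if p.p_within >= 1.0 and p.p_between >= 1.0:
        import warnings

        warnings.warn("degenerate norms config: every concept pair shares "
                      "features, network will be complete", stacklevel=2)
    rng = _substream(config.seed, _KEY_NORMS)
    concepts = sorted(checklist.items)
    feats: dict[str, dict[str, str]] = {}
    for c in concepts:
        f = {}
        for i in range(p.idiosyncratic_perceptual):
            f[f"perc:{c}:{i}"] = "perceptual"
        for i in range(p.idiosyncratic_functional):
            f[f"func:{c}:{i}"] = "functional"
        f[f"tax:is_{checklist.items[c].lower()}"] = "taxonomic"
        f[f"enc:about_{c}"] = "encyclopedic"
        feats[c] = f
    pairs = list(combinations(concepts, 2))
    u = rng.random(len(pairs))
    for (a, b), ua in zip(pairs, u):
        same = checklist.items[a] == checklist.items[b]
        if ua < (p.p_within if same else p.p_between):
            feats[a][f"shp:{a}|{b}"] = "perceptual"
            feats[b][f"shp:{a}|{b}"] = "perceptual"
            feats[a][f"shf:{a}|{b}"] = "functional"
            feats[b][f"shf:{a}|{b}"] = "functional"
    return FeatureNorms(features=feats)


def gen_children(
    config: SimConfig, checklist: ChecklistDefinition | None = None
) -> list[ChildVocabulary]:
    """Draw vocabulary sizes and per-child category-weighted word samples."""
    import warnings

    p = config.vocab
    if checklist is None:
        checklist = make_checklist()
    rng = _substream(config.seed, _KEY_CHILDREN)
    words = np.array(sorted(checklist.items))
    cats = np.array([checklist.items[w] for w in words])
    cat_names = sorted(set(cats))
    sizes_by_cat = {c: int((cats == c).sum()) for c in cat_names}
    base = np.array([sizes_by_cat[c] for c in cat_names], dtype=float)
    base /= base.sum()
    n_words = len(words)
    children = []
    for k in range(config.n_children):
        if p.min_words == p.max_words:  # degenerate distribution
            size = p.min_words
        else:
            while True:
                size = int(np.round(rng.lognormal(p.mu, p.sigma)))
                if p.min_words <= size <= p.max_words:
                    break
        if size > n_words:
            warnings.warn("requested vocabulary exceeds checklist; capped",
                          stacklevel=2)
            size = n_words
        if np.isfinite(p.concentration):
            w = rng.dirichlet(p.concentration * base)
        else:
            w = base
        cat_w = dict(zip(cat_names, w))
        probs = np.array([cat_w[c] / sizes_by_cat[c] for c in cats])
        probs /= probs.sum()
        chosen = rng.choice(n_words, size=size, replace=False, p=probs)
        children.append(
            ChildVocabulary(
                child_id=f"c{k:03d}", produced=frozenset(words[chosen])
            )
        )
    return children


def gen_design(config: SimConfig, child_id: str, child_index: int) -> pd.DataFrame:
    """One child's counterbalanced 24-trial design.

    Each of the 12 images appears four times — twice as target and twice as
    distractor, once per role in a related and in an unrelated pairing — and
    twice on each side of the screen.  Side assignment alternates coherently
    across the related/unrelated pairings sharing an image (the only
    arrangement consistent with full counterbalancing); whole blocks of
    yoked pairings flip side-polarity at random per child, and trial order
    is shuffled into four blocks of six.
    """
    rng = _substream(config.seed, _KEY_DESIGN, child_index)
    # side-consistency components over the yoked pairings
    components = [
        {"related": [("dog", "bird"), ("nose", "mouth")],
         "unrelated": [("nose", "bird"), ("mouth", "dog")]},
        {"related": [("banana", "apple"), ("juice", "milk")],
         "unrelated": [("banana", "juice"), ("apple", "milk")]},
        {"related": [("shoe", "diaper"), ("car", "airplane")],
         "unrelated": [("car", "shoe"), ("airplane", "diaper")]},
    ]
    rows = []
    for comp in components:
        flip = bool(rng.integers(0, 2))
        rel_side = "right" if flip else "left"
        unrel_side = "left" if flip else "right"
        for a, b in comp["related"]:
            rows.append({"condition": "related", "target": a, "distractor": b,
                         "target_side": rel_side})
            rows.append({"condition": "related", "target": b, "distractor": a,
                         "target_side": rel_side})
        for a, b in comp["unrelated"]:
            rows.append({"condition": "unrelated", "target": a, "distractor": b,
                         "target_side": unrel_side})
            rows.append({"condition": "unrelated", "target": b, "distractor": a,
                         "target_side": unrel_side})
    order = rng.permutation(len(rows))
    out = []
    for slot, idx in enumerate(order):
        r = dict(rows[idx])
        r["trial_id"] = f"{child_id}_t{slot:02d}"
        r["child_id"] = child_id
        r["block"] = slot // 6 + 1
        out.append(r)
    return pd.DataFrame(out)[
        ["trial_id", "child_id", "block", "condition",
         "target", "distractor", "target_side"]
    ]


def gen_ratings(
    config: SimConfig, children: list[ChildVocabulary]
) -> dict[tuple[str, str], int]:
    """Parental comprehension ratings (1-4) per child x experimental item.

    Produced items are rated 3-4 and unproduced 2-3 (comprehension usually
    precedes production); with the configured probability a rating drops to
    1 so the comprehension filter is exercised.
    """
    rng = _substream(config.seed, _KEY_RATINGS)
    ratings = {}
    items = sorted(EXPERIMENTAL_ITEMS)
    for child in children:
        for item in items:
            if rng.random() < config.low_rating_prob:
                ratings[(child.child_id, item)] = 1
            elif item in child.produced:
                ratings[(child.child_id, item)] = int(rng.integers(3, 5))
            else:
                ratings[(child.child_id, item)] = int(rng.integers(2, 4))
    return ratings


def draw_truth(config: SimConfig) -> SimTruth:
    """Realize the generating coefficients and per-item intercepts."""
    rng = _substream(config.seed, _KEY_TRUTH)
    g = config.gaze
    intercepts = {
        item: float(rng.normal(0.0, g.item_intercept_sd))
        for item in sorted(EXPERIMENTAL_ITEMS)
    }
    return SimTruth(
        beta0=g.beta0,
        beta_cond=g.beta_cond,
        beta={c: dict(v) for c, v in g.beta.items()},
        gamma=dict(g.gamma),
        item_intercepts=intercepts,
    )


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def trial_predictors(
    design: pd.DataFrame,
    metrics: dict[str, StructureMetrics],
    density: dict[str, DensityAssignment],
    groups: VocabGroupAssignment,
) -> pd.DataFrame:
    """Cohort-standardized generative predictors for each designed trial."""
    df = design.copy()
    df["gcc_raw"] = df["child_id"].map(lambda c: metrics[c].gcc)
    df["degree_raw"] = [
        metrics[c].degree[t] for c, t in zip(df["child_id"], df["target"])
    ]
    df["gcc_z"] = _zscore(df["gcc_raw"].to_numpy(float))
    df["degree_z"] = _zscore(df["degree_raw"].to_numpy(float))
    df["density_code"] = [
        DENSITY_CODE[density[c].condition[EXPERIMENTAL_ITEMS[t]]]
        for c, t in zip(df["child_id"], df["target"])
    ]
    df["group_code"] = df["child_id"].map(lambda c: GROUP_CODE[groups.group[c]])
    df["cond_code"] = df["condition"].map(COND_CODE)
    return df


def linear_predictor(pred: pd.DataFrame, truth: SimTruth) -> np.ndarray:
    """Per-trial generative log-odds eta of target over distractor."""
    eta = np.full(len(pred), truth.beta0, dtype=float)
    eta += truth.beta_cond * pred["cond_code"].to_numpy(float)
    for cond in ("related", "unrelated"):
        mask = (pred["condition"] == cond).to_numpy()
        if not mask.any():
            continue
        b = truth.beta[cond]
        struct = (
            b["gcc"] * pred.loc[mask, "gcc_z"].to_numpy(float)
            + b["degree"] * pred.loc[mask, "degree_z"].to_numpy(float)
            + b["density"] * pred.loc[mask, "density_code"].to_numpy(float)
        )
        mult = 1.0 + truth.gamma[cond] * pred.loc[mask, "group_code"].to_numpy(float)
        eta[mask] += struct * mult
    eta += pred["target"].map(truth.item_intercepts).to_numpy(float)
    return eta


def _stationary(eta: np.ndarray, offscreen: np.ndarray, other_share: float,
                preference: bool) -> np.ndarray:
    """Stationary distributions (n_trials, 4): T, D, OTHER, OFFSCREEN."""
    onscreen = 1.0 - offscreen
    other = onscreen * other_share
    aoi = onscreen - other
    if preference:
        p_t = aoi / (1.0 + np.exp(-eta))
    else:
        p_t = aoi * 0.5
    p_d = aoi - p_t
    return np.column_stack([p_t, p_d, other, offscreen])


def gen_gaze(
    config: SimConfig,
    design: pd.DataFrame,
    metrics: dict[str, StructureMetrics],
    density: dict[str, DensityAssignment],
    groups: VocabGroupAssignment,
    ratings: dict[tuple[str, str], int],
    truth: SimTruth | None = None,
) -> tuple[list[GazeTrial], SimTruth]:
    """Simulate every designed trial's 500 Hz four-state gaze stream.

    The chain starts from the neutral (pre-latency) stationary distribution;
    at each 2 ms step it stays put with ``stay_prob`` or resamples from the
    phase's stationary distribution — neutral before the preference latency,
    preference-weighted (odds exp(eta)) after.  A configured fraction of
    trials are "fussy", with most mass offscreen, to exercise the track-loss
    filter.
    """
    g = config.gaze
    if truth is None:
        truth = draw_truth(config)
    pred = trial_predictors(design, metrics, density, groups)
    eta = linear_predictor(pred, truth)
    n_trials = len(pred)
    n_steps = int(round(g.trial_duration_ms / SAMPLE_MS))
    latency_step = int(round(g.latency_ms / SAMPLE_MS))

    # per-trial substreams keyed by trial index: order-independent draws
    uniforms = np.empty((n_trials, n_steps + 2), dtype=np.float64)
    for i in range(n_trials):
        uniforms[i] = _substream(config.seed, _KEY_GAZE, i).random(n_steps + 2)

    fussy = uniforms[:, 0] < g.fussy_trial_prob
    offscreen = np.where(fussy, g.fussy_offscreen_rate, g.offscreen_rate)
    cum_pre = np.cumsum(
        _stationary(eta, offscreen, g.other_share, preference=False), axis=1
    )
    cum_post = np.cumsum(
        _stationary(eta, offscreen, g.other_share, preference=True), axis=1
    )

    states = np.empty((n_trials, n_steps), dtype=np.int8)
    state = (uniforms[:, 1][:, None] >= cum_pre).sum(axis=1).astype(np.int8)
    stay = g.stay_prob
    for k in range(n_steps):
        u = uniforms[:, k + 2]
        switch = u >= stay
        if switch.any():
            v = ((u[switch] - stay) / (1.0 - stay))[:, None]
            cum = cum_post if k >= latency_step else cum_pre
            state[switch] = (v >= cum[switch]).sum(axis=1).astype(np.int8)
        states[:, k] = state

    times = np.arange(n_steps) * SAMPLE_MS
    trials = []
    for i, row in enumerate(pred.itertuples(index=False)):
        trials.append(
            GazeTrial(
                trial_id=row.trial_id,
                child_id=row.child_id,
                condition=row.condition,
                target=row.target,
                distractor=row.distractor,
                comprehension_rating=ratings[(row.child_id, row.target)],
                times=times,
                states=states[i],
                target_side=row.target_side,
            )
        )
    return trials, truth


@dataclass
class Cohort:
    """A fully realized synthetic cohort plus its generating truth."""

    config: SimConfig
    checklist: ChecklistDefinition
    norms: FeatureNorms
    children: list[ChildVocabulary]
    density: dict[str, DensityAssignment]
    groups: VocabGroupAssignment
    metrics: dict[str, StructureMetrics]
    design: pd.DataFrame
    ratings: dict[tuple[str, str], int]
    trials: list[GazeTrial]
    truth: SimTruth


def simulate_cohort(
    config: SimConfig,
    norms: FeatureNorms | None = None,
    adjacency: NormsAdjacency | None = None,
    proportion_mode: str = "per-category-size",
) -> Cohort:
    """Run every generation stage and the structure measurements.

    ``norms``/``adjacency`` may be passed in to share one norms database
    across replicate cohorts (as a single study would).
    """
    checklist = make_checklist()
    if norms is None:
        norms = gen_norms(config, checklist)
    if adjacency is None:
        adjacency = NormsAdjacency(norms)
    children = gen_children(config, checklist)
    density = {
        c.child_id: assign_density(
            c.child_id, category_proportions(c, checklist, proportion_mode)
        )
        for c in children
    }
    groups = split_vocab_groups(children)
    targets = sorted(EXPERIMENTAL_ITEMS)
    metrics = {
        c.child_id: adjacency.child_metrics(c.child_id, set(c.produced), targets)
        for c in children
    }
    design = pd.concat(
        [gen_design(config, c.child_id, i) for i, c in enumerate(children)],
        ignore_index=True,
    )
    ratings = gen_ratings(config, children)
    truth = draw_truth(config)
    trials, _ = gen_gaze(config, design, metrics, density, groups, ratings, truth)
    return Cohort(
        config=config, checklist=checklist, norms=norms, children=children,
        density=density, groups=groups, metrics=metrics, design=design,
        ratings=ratings, trials=trials, truth=truth,
    )
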