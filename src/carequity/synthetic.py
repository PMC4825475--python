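"""Survey-like synthetic data from a known log-linear truth.

The original health-survey microdata is not publicly deposited, so every
pipeline stage is exercised against data simulated from an explicit
generative model: cell probabilities proportional to exp(sum of lambda
terms) over the categorical axes (reference-category coding by default,
reference = last category), multinomial sampling of frequency tables,
and respondent-level microdata with raw-coded SES items built around a
shared latent trait so that the composite-index machinery (binning,
scoring, tertiles, Cronbach's alpha) can be tested end to end.

The :func:`survey_like_spec` preset mimics the published survey's broad
structure — location mix, ~15% elderly, ~13% GP / ~6% specialist
visitors, SES gradient by location, pro-poor elderly GP utilization and
pro-rich young specialist utilization.  It is a demonstration preset,
not an assertion about the real survey.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .loglinear import GeneratingClass, Term
from .tables import SES, SURVEY_AXES, CategoricalAxis, FrequencyTable

__all__ = [
    "GenerativeSpec",
    "MicrodataSpec",
    "dummy_lambda",
    "cell_probabilities",
    "sample_table",
    "sample_microdata",
    "survey_like_spec",
]


def dummy_lambda(sizes: tuple[int, ...], contrasts) -> np.ndarray:
    """Build a reference-coded lambda array from its free contrasts.

    *contrasts* has shape ``tuple(s - 1 for s in sizes)``; entries where
    any axis sits at its reference (last) level are zero.
    """
    arr = np.zeros(sizes, dtype=float)
    block = np.asarray(contrasts, dtype=float)
    expected = tuple(s - 1 for s in sizes)
    if block.shape != expected:
        block = block.reshape(expected)
    arr[tuple(slice(0, s - 1) for s in sizes)] = block
    return arr


@dataclass(frozen=True)
class MicrodataSpec:
    """How respondent-level embellishment is generated around the cell draw.

    ``item_correlation`` is the target mean inter-item correlation of
    the four SES items (0.37 puts Cronbach's alpha near 0.70 for k=4);
    ``tertile_means``/``tertile_sd`` place the shared latent SES trait
    for low/middle/high respondents; ``visit_intensity`` is the Poisson
    mean of visits beyond the first for respondents who visited at all.
    """

    item_correlation: float = 0.37
    tertile_means: tuple[float, float, float] = (-1.2, 0.0, 1.2)
    tertile_sd: float = 0.55
    visit_intensity: float = 0.4
    location_ses_mix: Mapping[str, tuple[float, float, float]] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.item_correlation < 1.0:
            raise ValueError(
                f"item correlation target {self.item_correlation} is infeasible; "
                "need 0 <= rho < 1"
            )


@dataclass
class GenerativeSpec:
    """A log-linear truth: axes, generating class and lambda parameters.

    ``lambdas`` maps implied terms to full-shape arrays over the term's
    axes (axis order as in ``axes``).  Under dummy coding every entry
    touching a reference (last) level must be zero, so exponentiated
    contrasts are directly conditional odds ratios at reference strata.
    """

    axes: tuple[CategoricalAxis, ...]
    generating_class: GeneratingClass
    lambdas: dict[Term, np.ndarray]
    coding: str = "dummy"
    microdata: MicrodataSpec | None = None

    def __post_init__(self) -> None:
        self.axes = tuple(self.axes)
        if self.coding not in ("dummy", "deviation"):
            raise ValueError(f"unknown coding {self.coding!r}")
        names = [a.name for a in self.axes]
        implied = self.generating_class.implied_terms()
        sizes = {a.name: a.size for a in self.axes}
        clean: dict[Term, np.ndarray] = {}
        for term, arr in self.lambdas.items():
            term = Term(term)
            if term not in implied:
                raise ValueError(f"lambda term {sorted(term)} not implied by {self.generating_class}")
            order = [n for n in names if n in term]
            arr = np.asarray(arr, dtype=float)
            expected = tuple(sizes[n] for n in order)
            if arr.shape != expected:
                raise ValueError(
                    f"lambda for {sorted(term)} has shape {arr.shape}, expected {expected}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite lambda for {sorted(term)}")
            if self.coding == "dummy":
                for ax_i in range(arr.ndim):
                    ref_slice = arr[tuple(-1 if i == ax_i else slice(None) for i in range(arr.ndim))]
                    if not np.allclose(ref_slice, 0.0):
                        raise ValueError(
                            f"dummy-coded lambda for {sorted(term)} must vanish at "
                            f"reference levels (axis {order[ax_i]})"
                        )
            clean[term] = arr
        self.lambdas = clean

    # -- serialization -------------------------------------------------------

    def to_yaml(self) -> str:
        doc = {
            "axes": [{"name": a.name, "categories": list(a.categories)} for a in self.axes],
            "generating_class": [sorted(t) for t in self.generating_class],
            "coding": self.coding,
            "lambdas": {
                ",".join(sorted(t)): np.asarray(v).tolist() for t, v in self.lambdas.items()
            },
        }
        if self.microdata is not None:
            md = {
                "item_correlation": self.microdata.item_correlation,
                "tertile_means": list(self.microdata.tertile_means),
                "tertile_sd": self.microdata.tertile_sd,
                "visit_intensity": self.microdata.visit_intensity,
            }
            if self.microdata.location_ses_mix is not None:
                md["location_ses_mix"] = {
                    k: list(v) for k, v in self.microdata.location_ses_mix.items()
                }
            doc["microdata"] = md
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "GenerativeSpec":
        doc = yaml.safe_load(text)
        axes = tuple(
            CategoricalAxis(a["name"], tuple(a["categories"])) for a in doc["axes"]
        )
        md = None
        if "microdata" in doc:
            raw = dict(doc["microdata"])
            if "tertile_means" in raw:
                raw["tertile_means"] = tuple(raw["tertile_means"])
            if raw.get("location_ses_mix"):
                raw["location_ses_mix"] = {
                    k: tuple(v) for k, v in raw["location_ses_mix"].items()
                }
            md = MicrodataSpec(**raw)
        return cls(
            axes=axes,
            generating_class=GeneratingClass(doc["generating_class"]),
            lambdas={
                Term(k.split(",")): np.asarray(v, dtype=float)
                for k, v in doc.get("lambdas", {}).items()
            },
            coding=doc.get("coding", "dummy"),
            microdata=md,
        )


def cell_probabilities(spec: GenerativeSpec) -> FrequencyTable:
    """Normalized cell probabilities exp(sum of lambda terms) of the truth."""
    names = [a.name for a in spec.axes]
    logp = np.zeros(tuple(a.size for a in spec.axes))
    for term, arr in spec.lambdas.items():
        missing = tuple(i for i, n in enumerate(names) if n not in term)
        logp += np.expand_dims(arr, missing) if missing else arr
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    return FrequencyTable(spec.axes, p)


def _rng_streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def sample_table(spec: GenerativeSpec, n: int, seed: int) -> FrequencyTable:
    """Multinomial draw of *n* respondents over the spec's cell probabilities."""
    if n < 1:
        raise ValueError("n must be >= 1")
    p = cell_probabilities(spec)
    (rng,) = _rng_streams(seed, 1)
    counts = rng.multinomial(n, p.counts.ravel()).reshape(p.counts.shape)
    return FrequencyTable(spec.axes, counts.astype(float))


_LOCATION_CODE = {"peripheral": 1, "intermediate": 2, "central": 3}


def sample_microdata(
    spec: GenerativeSpec, n: int, seed: int, include_truth: bool = False
) -> pd.DataFrame:
    """Respondent-level survey rows drawn from the spec's joint distribution.

    Each respondent receives a (location, age, SES tertile, GP visit,
    SD visit) cell from the truth, then raw-coded SES items generated
    from a shared latent trait: item_j = z + e_j with z centred on the
    tertile mean, giving the configured mean inter-item correlation.
    Items are quantile-mapped onto the survey's raw code ranges
    (occupation 1-11, education 0-6, SEC cluster 1-10, rooms 0.5-9.5 in
    half-room steps); visit counts are 1 + Poisson(intensity) for
    visitors and 0 otherwise.

    Columns: location (1=peripheral..3=central), age (years),
    occupation, education, sec, rooms, gp_visits, sd_visits; with
    *include_truth*, also the generative ses_true/vis_gp/vis_sd labels.
    """
    if spec.microdata is None:
        raise ValueError("spec has no microdata embellishment")
    md = spec.microdata
    required = {a.name for a in SURVEY_AXES}
    have = {a.name for a in spec.axes}
    if not required <= have:
        raise ValueError(f"microdata sampling needs axes {sorted(required)}, spec has {sorted(have)}")

    p = cell_probabilities(spec)
    rng_cell, rng_age, rng_item, rng_visit = _rng_streams(seed, 4)
    flat = rng_cell.choice(p.counts.size, size=n, p=p.counts.ravel())
    idx = np.unravel_index(flat, p.counts.shape)
    level = {a.name: np.asarray(a.categories)[idx[i]] for i, a in enumerate(spec.axes)}

    ses_idx = np.select(
        [level["ses"] == c for c in SES.categories], list(range(3))
    ).astype(int)

    # latent SES trait shared by the four items
    mu = np.asarray(md.tertile_means, dtype=float)[ses_idx]
    z = mu + rng_item.normal(0.0, md.tertile_sd, size=n)
    # shared variance of z in the population (exact, from the ses marginal)
    ses_marg = p.collapse(["ses"]).counts
    mu_all = np.asarray(md.tertile_means, dtype=float)
    var_mu = float(np.sum(ses_marg * (mu_all - np.sum(ses_marg * mu_all)) ** 2))
    shared = var_mu + md.tertile_sd**2
    rho = md.item_correlation
    if rho == 0.0:
        items = rng_item.normal(0.0, 1.0, size=(n, 4))
        total_sd = 1.0
        mean_z = 0.0
    else:
        noise_sd = float(np.sqrt(shared * (1.0 - rho) / rho))
        items = z[:, None] + rng_item.normal(0.0, noise_sd, size=(n, 4))
        total_sd = float(np.sqrt(shared + noise_sd**2))
        mean_z = float(np.sum(ses_marg * mu_all))

    u = stats.norm.cdf((items - mean_z) / total_sd)
    occupation = 1 + np.minimum((u[:, 0] * 11).astype(int), 10)
    education = np.minimum((u[:, 1] * 7).astype(int), 6)
    sec = 1 + np.minimum((u[:, 2] * 10).astype(int), 9)
    rooms = 0.5 + np.round(u[:, 3] * 18) / 2.0  # 0.5 .. 9.5 in half-room steps

    age = np.where(
        level["age"] == "ge60",
        rng_age.integers(60, 86, size=n),
        rng_age.integers(20, 60, size=n),
    )

    def visit_counts(visited: np.ndarray) -> np.ndarray:
        extra = rng_visit.poisson(md.visit_intensity, size=n)
        return np.where(visited, 1 + extra, 0)

    out = pd.DataFrame(
        {
            "location": pd.Series(level["location"]).map(_LOCATION_CODE).to_numpy(),
            "age": age,
            "occupation": occupation,
            "education": education,
            "sec": sec,
            "rooms": rooms,
            "gp_visits": visit_counts(level["vis_gp"] == "yes"),
            "sd_visits": visit_counts(level["vis_sd"] == "yes"),
        }
    )
    if include_truth:
        out["ses_true"] = level["ses"]
        out["vis_gp"] = level["vis_gp"]
        out["vis_sd"] = level["vis_sd"]
    return out


# ---------------------------------------------------------------------------
# Demonstration preset
# ---------------------------------------------------------------------------

#: SES tertile mix (low, middle, high) by location used by the preset.
_PRESET_SES_MIX = {
    "peripheral": (0.55, 0.30, 0.15),
    "intermediate": (0.40, 0.33, 0.27),
    "central": (0.26, 0.32, 0.42),
}


def survey_like_spec(microdata: MicrodataSpec | None = None) -> GenerativeSpec:
    """A preset truth with the published survey's broad structure.

    Location mix and elderly shares follow the survey's demographics;
    visit effects mirror the published odds-ratio magnitudes (pro-poor
    elderly GP utilization around 1.8, pro-rich young specialist
    utilization around 0.5).  Magnitudes are presets for demonstration
    and testing, not estimates of the real survey.
    """
    L, A, S, G, V = "location", "age", "ses", "vis_gp", "vis_sd"
    mix = _PRESET_SES_MIX
    lam_s = [np.log(mix["central"][i] / mix["central"][2]) for i in range(2)]
    lam_ls = [
        [np.log(mix[loc][i] / mix[loc][2]) - lam_s[i] for i in range(2)]
        for loc in ("peripheral", "intermediate")
    ]
    lambdas = {
        Term([L]): dummy_lambda((3,), [np.log(0.158 / 0.535), np.log(0.307 / 0.535)]),
        # offset keeps the marginal elderly share near the survey's 15%
        # after the positive elderly-visit interactions add mass
        Term([A]): dummy_lambda((2,), [np.log(0.167 / 0.833) - 0.26]),
        Term([L, A]): dummy_lambda((3, 2), [[-0.415], [-0.231]]),
        Term([S]): dummy_lambda((3,), lam_s),
        Term([L, S]): dummy_lambda((3, 3), lam_ls),
        # axis order inside a term follows the table axis order, so vis_gp
        # precedes ses in the G-by-S blocks below
        Term([G]): dummy_lambda((2,), [np.log(0.10 / 0.90)]),
        Term([A, G]): dummy_lambda((2, 2), [[np.log(2.39)]]),
        Term([S, G]): dummy_lambda((2, 3), [[np.log(0.99), np.log(0.96)]]),
        Term([A, S, G]): dummy_lambda(
            (2, 2, 3), [[[np.log(1.84 / 0.99), np.log(1.57 / 0.96)]]]
        ),
        Term([V]): dummy_lambda((2,), [np.log(0.065 / 0.935)]),
        Term([A, V]): dummy_lambda((2, 2), [[np.log(2.13)]]),
        Term([S, V]): dummy_lambda((3, 2), [[np.log(0.48)], [np.log(0.78)]]),
        Term([A, S, V]): dummy_lambda(
            (2, 3, 2), [[[np.log(1.05 / 0.48)], [np.log(1.08 / 0.78)]]]
        ),
        Term([L, V]): dummy_lambda((3, 2), [[np.log(0.70)], [np.log(0.85)]]),
    }
    gc = GeneratingClass([[L, A, S], [A, S, G], [A, S, V], [L, V]])
    if microdata is None:
        microdata = MicrodataSpec(location_ses_mix=_PRESET_SES_MIX)
    elif microdata.location_ses_mix is None:
        microdata = replace(microdata, location_ses_mix=_PRESET_SES_MIX)
    return GenerativeSpec(
        axes=SURVEY_AXES,
        generating_class=gc,
        lambdas=lambdas,
        microdata=microdata,
    )
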