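"""Minute-wise SNR time courses and AICc-based linear mixed-model selection.

The temporal evolution of the tagged responses is summarised per subject as
SOI-averaged SNR in four sliding two-minute windows (power spectra of the
five 112-cycle minutes, averaged pairwise: minutes 1-2, 2-3, 3-4, 4-5), for
each stream type. A linear mixed model of SNR on the predictors STREAM,
MINUTES (categorical, continuous or quadratic coding) and, for the wake
session, the between-subject GROUP is then selected in two steps:

1. covariance structure — fit the saturated fixed model under REML for each
   candidate random-effect structure, keep the AICc minimiser (valid across
   REML fits because the fixed part is held constant);
2. fixed effects — with that structure, fit every admissible fixed-effect
   formula under ML and keep the AICc minimiser.

AICc = AIC + 2k(k+1)/(n-k-1) with n the number of observations and k the
number of estimated parameters (fixed effects, covariance parameters and the
residual variance). Model hierarchy is respected: an interaction is only
entertained together with its main effects. Candidates that fail to
converge are dropped with a warning.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .simulate import Recording, SensorArray
from .spectral import (
    average_epochs,
    combine_gradiometers,
    extract_epoch,
    foi_bin,
    power_spectrum,
    snr_spectrum,
)

__all__ = [
    "WINDOW_LABELS",
    "LMMResult",
    "minute_block_spectra",
    "window_pair_snr",
    "minute_windows",
    "candidate_random_structures",
    "candidate_fixed_models",
    "aicc",
    "select_lmm",
]

#: Two-minute averaging windows over the five 1-min blocks.
WINDOW_LABELS = ("1-2", "2-3", "3-4", "4-5")
_CYCLES_PER_MINUTE = 112  # 61.04 s


def minute_block_spectra(
    recordings: list[Recording],
    array: SensorArray,
    skip_tones: int = 12,
    n_minutes: int = 5,
):
    """Combined-gradiometer power spectrum of each 1-min block (112 cycles).

    Runs are averaged in the time domain per block position before the FFT.
    """
    block_ps = []
    for m in range(n_minutes):
        eps = [
            extract_epoch(
                rec,
                n_cycles=_CYCLES_PER_MINUTE,
                skip_tones=skip_tones,
                start_cycle=m * _CYCLES_PER_MINUTE,
            )
            for rec in recordings
        ]
        avg = average_epochs(eps).pick_types("grad1", "grad2")
        block_ps.append(combine_gradiometers(power_spectrum(avg), array))
    return block_ps


def window_pair_snr(block_ps, w: int, foi: float, n_neighbors: int = 40) -> np.ndarray:
    """Per-chipset SNR at ``foi`` for the two-minute window starting at block w.

    Power spectra of blocks w and w+1 are averaged before the neighbour
    ratio (40 neighbours, 20 per side, skipping the closest 2).
    """
    a, b = block_ps[w], block_ps[w + 1]
    avg = a.__class__(
        freqs=a.freqs,
        power=0.5 * (a.power + b.power),
        resolution=a.resolution,
        channels=a.channels,
        band=a.band,
    )
    snr = snr_spectrum(avg, n_neighbors=n_neighbors)
    return snr.snr[:, foi_bin(snr, foi)]


def minute_windows(
    recordings: list[Recording],
    soi_mask: np.ndarray,
    foi: float,
    array: SensorArray,
    n_neighbors: int = 40,
    skip_tones: int = 12,
    n_minutes: int = 5,
    block_ps=None,
) -> pd.DataFrame:
    """SOI-averaged SNR per two-minute window for one subject and stream.

    Each 1-min block spans 112 triple cycles (61.04 s). Runs are averaged in
    the time domain per block position, block power spectra are averaged
    over successive pairs, and SNR uses the 40-neighbour rule (20 per side,
    skipping the closest 2).
    """
    if n_minutes < 2:
        raise ValueError("need at least 2 minutes for one window pair")
    soi_mask = np.asarray(soi_mask, dtype=bool)
    if not soi_mask.any():
        raise ValueError("empty SOI mask")
    if block_ps is None:
        block_ps = minute_block_spectra(
            recordings, array, skip_tones=skip_tones, n_minutes=n_minutes
        )
    rows = []
    for w in range(n_minutes - 1):
        topo = window_pair_snr(block_ps, w, foi, n_neighbors=n_neighbors)
        rows.append(
            {
                "window": WINDOW_LABELS[w] if w < len(WINDOW_LABELS) else f"{w + 1}-{w + 2}",
                "minutes": w + 1,
                "snr": float(topo[soi_mask].mean()),
            }
        )
    return pd.DataFrame(rows)


def candidate_random_structures() -> list[tuple[str, str]]:
    """(label, re_formula) pairs: random intercept plus optional MINUTES
    and/or STREAM random slopes, always including the intercept."""
    return [
        ("intercept", "1"),
        ("intercept+minutes", "1 + minutes_c"),
        ("intercept+stream", "1 + stream_x"),
        ("intercept+minutes+stream", "1 + minutes_c + stream_x"),
    ]


_MINUTES_TERMS = {
    "cat": ("C(window)",),
    "cont": ("minutes_c",),
    "quad": ("minutes_lin", "minutes_quad"),
}


def _interactions(terms_a: tuple[str, ...], terms_b: tuple[str, ...]) -> tuple[str, ...]:
    return tuple(f"{a}:{b}" for a in terms_a for b in terms_b)


def candidate_fixed_models(session: str) -> list[tuple[str, str]]:
    """All admissible fixed-effect formulas for a session.

    Predictors are STREAM, MINUTES (three codings: categorical windows,
    continuous 1..4, orthogonal linear+quadratic polynomial) and, for the
    wake session, the between-subject GROUP. Interactions imply their main
    effects (and a three-way interaction implies all two-ways); the
    intercept-only model is always included.
    """
    if session not in ("sleep", "wake"):
        raise ValueError("session must be 'sleep' or 'wake'")
    with_group = session == "wake"
    models: list[tuple[str, str]] = [("intercept", "snr ~ 1")]

    factor_sets: list[dict] = []
    for m_enc in (None, "cat", "cont", "quad"):
        for s_in, g_in in itertools.product((False, True), repeat=2):
            if g_in and not with_group:
                continue
            present = {}
            if s_in:
                present["S"] = ("stream_x",)
            if m_enc is not None:
                present["M"] = _MINUTES_TERMS[m_enc]
            if g_in:
                present["G"] = ("group_x",)
            if not present:
                continue
            factor_sets.append({"enc": m_enc, "present": present})

    for spec in factor_sets:
        present = spec["present"]
        keys = sorted(present)
        pairs = list(itertools.combinations(keys, 2))
        for pair_subset in itertools.chain.from_iterable(
            itertools.combinations(pairs, r) for r in range(len(pairs) + 1)
        ):
            threeway_options = [False]
            if len(keys) == 3 and len(pair_subset) == len(pairs):
                threeway_options = [False, True]
            for threeway in threeway_options:
                terms: list[str] = []
                for k in keys:
                    terms.extend(present[k])
                for a, b in pair_subset:
                    terms.extend(_interactions(present[a], present[b]))
                if threeway:
                    terms.extend(
                        f"{x}:{y}:{z}"
                        for x in present[keys[0]]
                        for y in present[keys[1]]
                        for z in present[keys[2]]
                    )
                label_main = "+".join(
                    (k if k != "M" else f"M[{spec['enc']}]") for k in keys
                )
                label_int = "+".join("".join(p) for p in pair_subset)
                label = label_main + (f"|{label_int}" if label_int else "")
                if threeway:
                    label += "|SMG" if not with_group else "|" + "".join(keys)
                models.append((label, "snr ~ " + " + ".join(terms)))
    return models


def aicc(llf: float, k: int, n: int) -> float:
    """Small-sample-corrected Akaike criterion."""
    aic = -2.0 * llf + 2.0 * k
    if n - k - 1 <= 0:
        return np.inf
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def prepare_table(table: pd.DataFrame, session: str) -> pd.DataFrame:
    """Add the numeric codings the model formulas expect.

    ``stream_x``: STAT=1, RDM=0; ``group_x``: exposure=1; ``minutes_c``:
    window index 1..4; ``minutes_lin``/``minutes_quad``: orthogonal
    polynomial contrasts over the four windows.
    """
    t = table.copy()
    required = {"subject", "window", "stream", "snr"}
    missing = required - set(t.columns)
    if missing:
        raise ValueError(f"dynamics table lacks columns {sorted(missing)}")
    t["stream_x"] = (t["stream"].astype(str).str.upper() == "STAT").astype(float)
    if session == "wake":
        if "group" not in t.columns:
            raise ValueError("wake-session table needs a 'group' column")
        t["group_x"] = (t["group"].astype(str) == "exposure").astype(float)
    order = {lab: i + 1 for i, lab in enumerate(WINDOW_LABELS)}
    t["minutes_c"] = t["window"].map(order).astype(float)
    lin = {1: -3.0, 2: -1.0, 3: 1.0, 4: 3.0}
    quad = {1: 1.0, 2: -1.0, 3: -1.0, 4: 1.0}
    t["minutes_lin"] = t["minutes_c"].map(lin) / np.sqrt(20.0)
    t["minutes_quad"] = t["minutes_c"].map(quad) / 2.0
    return t


@dataclass
class LMMResult:
    selected_random: str
    selected_fixed: str
    re_formula: str
    fixed_formula: str
    coefficients: pd.DataFrame  # estimate, se, z, p per fixed effect
    aicc_random: dict[str, float]
    aicc_fixed: dict[str, float]
    p_values: dict[str, float]
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "selected_random": self.selected_random,
            "selected_fixed": self.selected_fixed,
            "re_formula": self.re_formula,
            "fixed_formula": self.fixed_formula,
            "coefficients": self.coefficients.to_dict(orient="index"),
            "aicc_random": self.aicc_random,
            "aicc_fixed": self.aicc_fixed,
            "p_values": self.p_values,
            "warnings": self.warnings,
        }


def _fit(formula: str, data: pd.DataFrame, re_formula: str, reml: bool):
    model = smf.mixedlm(formula, data, groups=data["subject"], re_formula=re_formula)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            res = model.fit(reml=reml, maxiter=200)
        except np.linalg.LinAlgError:
            res = model.fit(reml=reml, method=["lbfgs", "powell"], maxiter=200)
    return res


def _n_params(res) -> int:
    # fixed effects + random-effect covariance entries (+ variance
    # components) + residual variance
    return len(res.params) + 1


def select_lmm(
    table: pd.DataFrame,
    session: str,
    random_candidates: list[tuple[str, str]] | None = None,
    fixed_candidates: list[tuple[str, str]] | None = None,
) -> LMMResult:
    """Two-step AICc selection of the mixed model for a dynamics table."""
    data = prepare_table(table, session)
    if random_candidates is None:
        random_candidates = candidate_random_structures()
    if fixed_candidates is None:
        fixed_candidates = candidate_fixed_models(session)
    saturated = "snr ~ stream_x * C(window)"
    if session == "wake":
        saturated += " * group_x"
    notes: list[str] = []

    aicc_random: dict[str, float] = {}
    for label, rf in random_candidates:
        try:
            res = _fit(saturated, data, rf, reml=True)
            if not res.converged or not np.isfinite(res.llf):
                raise RuntimeError("non-convergence")
            aicc_random[label] = aicc(res.llf, _n_params(res), len(data))
        except Exception as exc:  # noqa: BLE001 - candidate dropped, not fatal
            notes.append(f"random structure {label!r} dropped: {exc}")
            warnings.warn(f"random structure {label!r} dropped: {exc}", stacklevel=2)
    if not aicc_random:
        raise RuntimeError("no random-effect structure converged")
    sel_random = min(aicc_random, key=aicc_random.get)
    re_formula = dict(random_candidates)[sel_random]

    aicc_fixed: dict[str, float] = {}
    fits: dict[str, object] = {}
    for label, formula in fixed_candidates:
        try:
            res = _fit(formula, data, re_formula, reml=False)
            if not res.converged or not np.isfinite(res.llf):
                raise RuntimeError("non-convergence")
            aicc_fixed[label] = aicc(res.llf, _n_params(res), len(data))
            fits[label] = res
        except Exception as exc:  # noqa: BLE001
            notes.append(f"fixed model {label!r} dropped: {exc}")
            warnings.warn(f"fixed model {label!r} dropped: {exc}", stacklevel=2)
    if not aicc_fixed:
        raise RuntimeError("no fixed-effect model converged")
    sel_fixed = min(aicc_fixed, key=aicc_fixed.get)
    best = fits[sel_fixed]

    fe = best.fe_params
    se = best.bse_fe
    z = fe / se
    from scipy import stats as sps

    p = 2.0 * sps.norm.sf(np.abs(z))
    coeff = pd.DataFrame(
        {"estimate": fe, "se": se, "z": z, "p": p}, index=fe.index
    )
    return LMMResult(
        selected_random=sel_random,
        selected_fixed=sel_fixed,
        re_formula=re_formula,
        fixed_formula=dict(fixed_candidates)[sel_fixed],
        coefficients=coeff,
        aicc_random=aicc_random,
        aicc_fixed=aicc_fixed,
        p_values={name: float(pv) for name, pv in zip(fe.index, p)},
        warnings=notes,
    )
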