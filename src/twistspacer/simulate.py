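"""Synthetic-data generators emulating the three experimental input kinds.

Every pipeline in this package can be exercised without any external dataset:
this module generates (a) in vitro sigma-titration activity tables, (b)
plate-reader reporter trajectories under superhelical shocks, and (c)
genome-scale promoter maps with differential-response tables, all with the
statistical structure of the real assays (model-driven means, per-promoter
spread of the spacer-independent response, replicate measurement noise, a
spacer-length distribution peaked at 17 nt).  Noise-free limits of every
generator are exactly invertible by the matching analysis pipeline.

All randomness flows through an explicit integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .invivo import ReporterTimeSeries
from .torsion import (
    DEFAULT_PARAMS,
    PromoterEnergyTerms,
    ShockCondition,
    TwistParameters,
    logfc_under_shock,
    transcription_rate,
)

__all__ = [
    "CohortSpec",
    "GrowthParams",
    "simulate_invitro",
    "simulate_reporter",
    "simulate_genome_cohort",
]

#: default spacer-length probabilities over 15-19 nt, peaked at 17 (27% mode,
#: matching the modal frequency among sigma70 promoters); the remaining masses
#: are illustrative configuration, not a claim about any curated map.
DEFAULT_LENGTH_DIST = {15: 0.14, 16: 0.14, 17: 0.27, 18: 0.25, 19: 0.20}


def simulate_invitro(
    lengths,
    sigma_grid,
    terms: dict[int, PromoterEnergyTerms] | PromoterEnergyTerms | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    params: TwistParameters = DEFAULT_PARAMS,
    promoter_id: str = "synthP",
) -> pd.DataFrame:
    """Model-driven sigma-titration activity table (in vitro dialect).

    Activity = thermodynamic transcription rate times log-normal measurement
    noise of log-scale sd ``noise_sd``.  The reference spacer (``params.n_ref``)
    is always included at every sigma.  ``terms`` may be a single
    :class:`PromoterEnergyTerms` or a per-length mapping (to give each variant
    its own ``k0``/``q_sp``).
    """
    rng = np.random.default_rng(seed)
    lengths = sorted(set(int(n) for n in lengths) | {params.n_ref})
    rows = []
    for n in lengths:
        if isinstance(terms, dict):
            t = terms.get(n, PromoterEnergyTerms())
        elif terms is not None:
            t = terms
        else:
            t = PromoterEnergyTerms()
        for s in sigma_grid:
            rate = transcription_rate(s, n, t, params)
            # q_sp shifts variant expression relative to the reference
            if n != params.n_ref:
                rate *= np.exp(t.q_sp)
            noise = np.exp(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 1.0
            rows.append(
                {
                    "promoter_id": f"{promoter_id}_{n}",
                    "sigma": float(s),
                    "spacer_len": n,
                    "activity": float(rate * noise),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GrowthParams:
    """Logistic growth of the culture: OD(t) = K / (1 + ((K-od0)/od0) e^{-rt})."""

    od0: float = 0.05
    od_max: float = 1.5
    rate: float = 0.02  # per minute (~35 min doubling early on)

    def od(self, t: np.ndarray) -> np.ndarray:
        a = (self.od_max - self.od0) / self.od0
        return self.od_max / (1.0 + a * np.exp(-self.rate * np.asarray(t, float)))


def _reporter_signal(
    times: np.ndarray,
    production: np.ndarray,
    lifetime: float,
) -> np.ndarray:
    """First-order reporter accumulation: dL/dt = p(t) - L / lifetime.

    Integrated exactly on each sampling step assuming piecewise-constant
    production; ``lifetime = 0`` is the no-buffering limit where the signal
    tracks production instantaneously.
    """
    if lifetime <= 0:
        return production.copy()
    lum = np.empty_like(production)
    lum[0] = production[0] * lifetime  # steady state at start
    for i in range(1, len(times)):
        dt = times[i] - times[i - 1]
        decay = np.exp(-dt / lifetime)
        lum[i] = lum[i - 1] * decay + production[i - 1] * lifetime * (1.0 - decay)
    return lum


def simulate_reporter(
    terms: PromoterEnergyTerms,
    shock: ShockCondition,
    spacer_length: int,
    shock_time: float = 120.0,
    t_max: float = 300.0,
    dt: float = 5.0,
    growth: GrowthParams = GrowthParams(),
    reporter_lifetime: float = 45.0,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
    params: TwistParameters = DEFAULT_PARAMS,
    promoter_id: str = "synthP",
    treatment: str = "drug",
) -> tuple[list[ReporterTimeSeries], list[ReporterTimeSeries]]:
    """Treated and vehicle reporter trajectories for one promoter variant.

    Per-cell promoter activity is constant before the shock and switches by
    the model fold-change ``exp(logFC(shock, n))`` at ``shock_time``; the
    vehicle arm receives ``delta_sigma = 0``.  Luminescence is the activity
    signal (activity times OD) filtered through first-order reporter decay
    with mean ``reporter_lifetime`` (the ~45 min luciferase lifetime that
    buffers repressive responses), times log-normal measurement noise.

    Returns ``(treated, vehicle)`` lists of ``n_replicates`` series each.
    """
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, t_max + dt / 2, dt)
    od = growth.od(times)
    fc = float(np.exp(logfc_under_shock(shock, spacer_length, terms, params)))

    def make(arm_fc: float, label: str, rep: int) -> ReporterTimeSeries:
        activity = np.where(times < shock_time, 1.0, arm_fc) * terms.k0
        production = activity * od
        lum = _reporter_signal(times, production, reporter_lifetime)
        if noise_sd > 0:
            lum = lum * np.exp(rng.normal(0.0, noise_sd, size=lum.shape))
        return ReporterTimeSeries(
            times=times.copy(),
            od=od.copy(),
            lum=lum,
            promoter_id=promoter_id,
            spacer_length=spacer_length,
            treatment=label,
            shock_time=shock_time,
            replicate=rep,
        )

    treated = [make(fc, treatment, r) for r in range(n_replicates)]
    vehicle = [make(1.0, "vehicle", r) for r in range(n_replicates)]
    return treated, vehicle


def reporter_to_frame(series: list[ReporterTimeSeries]) -> pd.DataFrame:
    """Flatten trajectories into the long-format reporter TSV dialect."""
    frames = []
    for s in series:
        frames.append(
            pd.DataFrame(
                {
                    "time_min": s.times,
                    "od": s.od,
                    "lum": s.lum,
                    "promoter_id": s.promoter_id,
                    "spacer_len": s.spacer_length,
                    "treatment": s.treatment,
                    "replicate": s.replicate,
                    "shock_time_min": s.shock_time,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a synthetic genome-scale cohort.

    ``r_sc_mean``/``r_sc_sd`` describe the promoter-to-promoter spread of the
    spacer-independent response term (k_B*T); it appears only when a shock is
    applied (``delta_sigma != 0``) -- an unshocked cohort has no true response.
    ``replicate_noise_sd`` is log-scale measurement noise per replicate;
    p-values come from per-promoter replicate t-tests against zero,
    Benjamini-Hochberg adjusted.  The default cohort size of 420 promoters
    leaves roughly 300 responsive (padj < 0.05) under the default relaxation
    shock, the scale of a curated-map analysis.
    """

    n_promoters: int = 420
    spacer_length_distribution: dict = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_DIST)
    )
    sigma0: float = -0.06
    delta_sigma: float = 0.03
    r_sc_mean: float = 0.0
    r_sc_sd: float = 0.5
    replicate_noise_sd: float = 0.2
    n_replicates: int = 3
    gc_discriminator: float = 0.45
    gc_shift_16: float = 0.0
    frac_minus_strand: float = 0.4

    def __post_init__(self) -> None:
        probs = np.array(list(self.spacer_length_distribution.values()), float)
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError("spacer length probabilities must sum to 1")
        if self.r_sc_sd < 0 or self.replicate_noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")


_M35_CONSENSUS = "TTGACA"
_M10_CONSENSUS = "TATAAT"
_BASES = np.array(list("ACGT"))


def _random_seq(rng, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def _mutated_hexamer(rng, consensus: str, n_mut: int = 1) -> str:
    s = list(consensus)
    for i in rng.choice(len(s), size=n_mut, replace=False):
        s[i] = rng.choice([b for b in "ACGT" if b != s[i]])
    return "".join(s)


def simulate_genome_cohort(
    spec: CohortSpec,
    seed: int,
    params: TwistParameters = DEFAULT_PARAMS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic promoter map plus differential-response table.

    Each promoter draws a spacer length from the cohort distribution and a
    spacer-independent response term ``R_sc,i ~ N(r_sc_mean, r_sc_sd)``; its
    true log fold-change is ``-R_sc,i - ddG_or(delta_sigma, n_i)``.  Observed
    replicates add log-scale noise; the reported logfc is the replicate mean
    and the adjusted p-value a BH-corrected one-sample t-test.  Hexamer,
    spacer and discriminator sequences are generated with configurable G/C
    composition (``gc_shift_16`` enriches 16-nt discriminators).

    Returns ``(promoter_map, responses)`` in the TSV dialects of the genome
    pipeline.
    """
    rng = np.random.default_rng(seed)
    m = spec.n_promoters
    lengths_avail = np.array(sorted(spec.spacer_length_distribution), int)
    probs = np.array(
        [spec.spacer_length_distribution[int(n)] for n in lengths_avail], float
    )
    n_i = rng.choice(lengths_avail, size=m, p=probs)

    if spec.delta_sigma == 0.0:
        r_sc = np.zeros(m)  # no superhelical shift -> no true response
    else:
        r_sc = rng.normal(spec.r_sc_mean, spec.r_sc_sd, size=m)
    cond = ShockCondition(sigma0=spec.sigma0, delta_sigma=spec.delta_sigma)
    ddg = np.asarray(
        logfc_under_shock(cond, n_i, PromoterEnergyTerms(r_sc=0.0), params)
    )
    true_logfc = -r_sc + ddg  # ddg already carries the minus sign of the energy

    reps = true_logfc[:, None] + rng.normal(
        0.0, spec.replicate_noise_sd, size=(m, spec.n_replicates)
    )
    obs_logfc = reps.mean(axis=1)
    sd = reps.std(axis=1, ddof=1)
    se = sd / np.sqrt(spec.n_replicates)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, obs_logfc / se, np.inf * np.sign(obs_logfc))
    pvals = 2 * stats.t.sf(np.abs(tstat), spec.n_replicates - 1)
    padj = multipletests(pvals, method="fdr_bh")[1]

    # --- promoter map ----------------------------------------------------
    strand = np.where(rng.random(m) < spec.frac_minus_strand, "-", "+")
    disc_len = rng.integers(5, 9, size=m)
    start = 1000
    rows = []
    for i in range(m):
        pid = f"SP{i:04d}"
        n = int(n_i[i])
        gc_disc = spec.gc_discriminator + (spec.gc_shift_16 if n == 16 else 0.0)
        gc_disc = min(max(gc_disc, 0.0), 1.0)
        m35_seq = _mutated_hexamer(rng, _M35_CONSENSUS)
        m10_seq = _mutated_hexamer(rng, _M10_CONSENSUS)
        spacer_seq = _random_seq(rng, n)
        disc_seq = _random_seq(rng, int(disc_len[i]), gc=gc_disc)
        if strand[i] == "+":
            m35_start = start
            m35_end = m35_start + 5
            m10_start = m35_end + n + 1
            m10_end = m10_start + 5
            tss = m10_end + int(disc_len[i]) + 1
        else:
            # mirrored on the genomic axis: -10 at lower coordinates
            m10_start = start
            m10_end = m10_start + 5
            m35_start = m10_end + n + 1
            m35_end = m35_start + 5
            tss = m10_start - int(disc_len[i]) - 1
        rows.append(
            {
                "promoter_id": pid,
                "sigma_factor": "sigma70",
                "tss": tss,
                "strand": strand[i],
                "m35_start": m35_start,
                "m35_end": m35_end,
                "m35_seq": m35_seq,
                "m10_start": m10_start,
                "m10_end": m10_end,
                "m10_seq": m10_seq,
                "spacer_len": n,
                "spacer_seq": spacer_seq,
                "discriminator_seq": disc_seq,
            }
        )
        start += 200
    promoters = pd.DataFrame(rows)
    responses = pd.DataFrame(
        {
            "promoter_id": promoters["promoter_id"],
            "logfc": obs_logfc,
            "padj": padj,
            "true_logfc": true_logfc,
            "r_sc": r_sc,
        }
    )
    return promoters, responses
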