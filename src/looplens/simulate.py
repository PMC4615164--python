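"""Mechanistic simulator of the crosslink → RNase → pulldown → qPCR assay.

The generative model, per mRNA molecule:

1. **State.** The molecule is in one of four configurations, drawn from
   per-transcript probabilities: ``closed`` (cap factor and PAB1 engaged,
   ends bridged into a loop), ``cap_only`` (cap factor engaged, open),
   ``tail_only`` (PAB1 engaged, open), or ``free`` (no factor).
2. **Fragmentation.** RNase cuts fall as a homogeneous Poisson process with
   rate λ (cuts/nt) along the transcript; fragments are the maximal uncut
   intervals. An amplicon is amplifiable on a molecule iff no cut falls
   strictly inside it, hence P(survive) = exp(-λ·span).
3. **Capture (IP channel).** Pulling down a tagged factor retains the
   fragment carrying the factor's anchor — the 5'-most fragment for
   eIF4E/eIF4G, the 3'-most for PAB1 — whenever the molecule's state
   includes that factor. For a ``closed`` molecule the *opposite*-end
   anchor fragment is additionally retained with co-capture efficiency c
   (the bridged complex survives washing imperfectly). Every other fragment
   is retained with nonspecific background probability β. The input channel
   is an aliquot of the same digestion: all fragments.
4. **qPCR.** Per sample × assay the amplifiable captured count N becomes
   Ct = intercept_a - ln(N)/ln(E_a) + Normal(0, σ) per technical replicate;
   a zero count is an undetermined (missing) Ct. Assay efficiencies E_a and
   intercepts are drawn once per dataset, so the per-assay scale is
   arbitrary and must cancel downstream. A dilution series is generated
   from the same E_a.

Closed-form expectations for every assay's IP/Input ratio are provided in
:func:`expected_enrichment` (derivation in its docstring) and serve as the
analytic oracle against the Monte-Carlo path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CAP_FACTORS = ("eIF4E", "eIF4G")
TAIL_FACTORS = ("PAB1",)

# molecule state codes
CLOSED, CAP_ONLY, TAIL_ONLY, FREE = 0, 1, 2, 3
STATE_NAMES = {CLOSED: "closed", CAP_ONLY: "cap_only", TAIL_ONLY: "tail_only", FREE: "free"}


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class TranscriptSim:
    """One simulated transcript: length, state probabilities, assay layout.

    ``assays`` is a tuple of (assay_id, start, end, region_class); when
    omitted, :func:`default_assay_layout` provides the standard design of
    five 70-nt amplicons (one per end plus three internal).
    """

    transcript_id: str
    length: int
    p_closed: float
    p_cap_only: float
    p_tail_only: float
    assays: tuple[tuple[str, int, int, str], ...] | None = None

    @property
    def p_free(self) -> float:
        return 1.0 - self.p_closed - self.p_cap_only - self.p_tail_only

    @property
    def closed_fraction_cap(self) -> float:
        """True closed-loop fraction among cap-factor-engaged molecules."""
        engaged = self.p_closed + self.p_cap_only
        return self.p_closed / engaged if engaged > 0 else float("nan")

    @property
    def closed_fraction_tail(self) -> float:
        """True closed-loop fraction among PAB1-engaged molecules."""
        engaged = self.p_closed + self.p_tail_only
        return self.p_closed / engaged if engaged > 0 else float("nan")

    @staticmethod
    def from_closed_fraction(
        transcript_id: str,
        length: int,
        closed_fraction: float,
        cap_engaged: float = 0.5,
        p_tail_only: float = 0.3,
    ) -> "TranscriptSim":
        """Build state probabilities from the cap-side closed fraction.

        ``cap_engaged`` is the fraction of molecules bound by the cap factor
        (closed + cap_only); ``closed_fraction`` of those are looped.
        """
        return TranscriptSim(
            transcript_id=transcript_id,
            length=length,
            p_closed=cap_engaged * closed_fraction,
            p_cap_only=cap_engaged * (1.0 - closed_fraction),
            p_tail_only=p_tail_only,
        )


def default_assay_layout(transcript_id: str, length: int, span: int = 70) -> tuple:
    """Five amplicons: 2 close to the ends, 3 internal, each ``span`` nt."""
    mids = [int(round(f * (length - span))) for f in (0.25, 0.5, 0.75)]
    layout = [
        (f"{transcript_id}_5p", 0, span, "five_prime"),
        (f"{transcript_id}_i1", mids[0], mids[0] + span, "internal"),
        (f"{transcript_id}_i2", mids[1], mids[1] + span, "internal"),
        (f"{transcript_id}_i3", mids[2], mids[2] + span, "internal"),
        (f"{transcript_id}_3p", length - span, length, "three_prime"),
    ]
    return tuple(layout)


@dataclass(frozen=True)
class Condition:
    """A growth condition; fields set to None inherit the global value.

    ``p_closed_scale`` multiplies every transcript's p_closed (the freed
    probability mass moves to cap_only), letting a condition shift loop
    prevalence without rewriting the transcript table.
    """

    name: str = "steady"
    cut_rate: float | None = None
    co_capture_eff: dict | float | None = None
    background: float | None = None
    p_closed_scale: float = 1.0


@dataclass(frozen=True)
class SimulationConfig:
    """Full generative parameter set; defaults are the study design.

    The defaults mirror the assay this simulator emulates: ~16 yeast
    transcripts probed by 5 amplicons each (two ends, three internal, each
    ≤75 bp), 3 technical qPCR replicates, 3 biological replicates, IP vs
    matched RNase-digested input, cap-side (eIF4E) and tail-side (PAB1)
    pulldowns at steady state.
    """

    transcripts: tuple[TranscriptSim, ...]
    factors: tuple[str, ...] = ("eIF4E", "PAB1")
    conditions: tuple[Condition, ...] = (Condition("steady"),)
    cut_rate: float = 0.01            # cuts/nt; a 70-nt amplicon survives ~50%
    co_capture_eff: dict | float = 0.8
    background: float = 0.002         # nonspecific per-fragment capture
    n_molecules: int = 20000          # molecules per transcript per replicate
    ct_noise_sd: float = 0.15         # cycles
    n_tech: int = 3
    n_bio: int = 3
    efficiency_range: tuple[float, float] = (1.85, 2.0)
    intercept_range: tuple[float, float] = (26.0, 30.0)
    dilution_levels: tuple[float, ...] = (1.0, 0.25, 0.0625, 0.015625)

    def co_capture_for(self, factor: str, condition: Condition | None = None) -> float:
        cc = self.co_capture_eff
        if condition is not None and condition.co_capture_eff is not None:
            cc = condition.co_capture_eff
        return float(cc[factor]) if isinstance(cc, dict) else float(cc)

    def cut_rate_for(self, condition: Condition | None = None) -> float:
        if condition is not None and condition.cut_rate is not None:
            return float(condition.cut_rate)
        return float(self.cut_rate)

    def background_for(self, condition: Condition | None = None) -> float:
        if condition is not None and condition.background is not None:
            return float(condition.background)
        return float(self.background)

    def transcript_in(self, tr: TranscriptSim, condition: Condition) -> TranscriptSim:
        """Apply the condition's p_closed_scale to one transcript."""
        if condition.p_closed_scale == 1.0:
            return tr
        new_closed = tr.p_closed * condition.p_closed_scale
        return replace(tr, p_closed=new_closed, p_cap_only=tr.p_cap_only + tr.p_closed - new_closed)

    def validate(self) -> None:
        if not self.transcripts:
            raise ValueError("config: no transcripts")
        ids = [t.transcript_id for t in self.transcripts]
        if len(set(ids)) != len(ids):
            raise ValueError("config: duplicate transcript ids")
        for tr in self.transcripts:
            probs = (tr.p_closed, tr.p_cap_only, tr.p_tail_only, tr.p_free)
            if any(p < -1e-12 or p > 1 + 1e-12 for p in probs):
                raise ValueError(f"config: state probabilities of '{tr.transcript_id}' outside [0, 1]: {probs}")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"config: state probabilities of '{tr.transcript_id}' do not sum to 1")
            for aid, s, e, _cls in self.assays_of(tr):
                if not (0 <= s < e <= tr.length):
                    raise ValueError(f"config: assay '{aid}' coordinates outside transcript")
        if self.cut_rate <= 0:
            raise ValueError("config: cut_rate must be > 0")
        for cond in self.conditions:
            for factor in self.factors:
                c = self.co_capture_for(factor, cond)
                if not 0 <= c <= 1:
                    raise ValueError(f"config: co_capture_eff for {factor} outside [0, 1]")
            b = self.background_for(cond)
            if not 0 <= b <= 1:
                raise ValueError("config: background outside [0, 1]")
        if self.ct_noise_sd < 0:
            raise ValueError("config: ct_noise_sd must be >= 0")
        if self.n_tech < 1 or self.n_bio < 1 or self.n_molecules < 1:
            raise ValueError("config: replicate and molecule counts must be positive")
        for factor in self.factors:
            if factor not in CAP_FACTORS + TAIL_FACTORS:
                raise ValueError(f"config: unknown factor '{factor}'")
        if len(self.dilution_levels) < 3:
            raise ValueError("config: need >=3 dilution levels")

    def assays_of(self, tr: TranscriptSim) -> tuple:
        return tr.assays if tr.assays is not None else default_assay_layout(tr.transcript_id, tr.length)


def default_config(n_transcripts: int = 16, **overrides) -> SimulationConfig:
    """The study-design default: transcripts whose cap-side closed-loop
    fractions span 0.05–0.8, mirroring the wide between-mRNA spread the
    assay is built to detect."""
    rng = np.random.default_rng(20150331)  # fixed: lengths are part of the design, not noise
    fractions = np.linspace(0.05, 0.8, n_transcripts)
    lengths = rng.integers(900, 3000, n_transcripts)
    transcripts = tuple(
        TranscriptSim.from_closed_fraction(f"TX{i + 1:02d}", int(lengths[i]), float(fractions[i]))
        for i in range(n_transcripts)
    )
    return replace(SimulationConfig(transcripts=transcripts), **overrides) if overrides else SimulationConfig(
        transcripts=transcripts
    )


def profile_demo_config() -> SimulationConfig:
    """A single-transcript exemplar of the canonical positional profiles.

    Cap-side closed fraction 0.35; the PAB1-side co-capture efficiency is
    set so the ideal PAB1 5'/3' ratio is 0.06 — i.e. a cap-factor pulldown
    shows both ends enriched over internal amplicons, while a PAB1 pulldown
    shows a strong 3' and a weak (6%) 5' signal.
    """
    tr = TranscriptSim.from_closed_fraction("SSC1like", 2000, closed_fraction=0.35)
    c_pab = 0.06 * (tr.p_closed + tr.p_tail_only) / tr.p_closed
    return SimulationConfig(
        transcripts=(tr,),
        factors=("eIF4E", "eIF4G", "PAB1"),
        co_capture_eff={"eIF4E": 1.0, "eIF4G": 1.0, "PAB1": c_pab},
        background=0.002,
    )


# ---------------------------------------------------------------------------
# single-molecule reference operations (unit-testable, mirror the fast path)


def fragment(length: float, cut_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Poisson-process cut positions (sorted) partitioning [0, length)."""
    if cut_rate <= 0:
        raise ValueError("cut_rate must be > 0")
    k = rng.poisson(cut_rate * length)
    return np.sort(rng.uniform(0.0, length, k))


def fragments_from_cuts(cuts: np.ndarray, length: float) -> list[tuple[float, float]]:
    """Maximal uncut intervals delimited by the cut positions."""
    bounds = np.concatenate(([0.0], np.asarray(cuts, float), [length]))
    return [(float(a), float(b)) for a, b in zip(bounds[:-1], bounds[1:])]


def assign_state(tr: TranscriptSim, rng: np.random.Generator) -> int:
    """Multinomial draw of the molecule configuration."""
    u = rng.random()
    if u < tr.p_closed:
        return CLOSED
    if u < tr.p_closed + tr.p_cap_only:
        return CAP_ONLY
    if u < tr.p_closed + tr.p_cap_only + tr.p_tail_only:
        return TAIL_ONLY
    return FREE


def capture(
    fragments: list[tuple[float, float]],
    state: int,
    factor: str,
    co_capture_eff: float,
    background: float,
    rng: np.random.Generator,
) -> list[bool]:
    """Which fragments the IP retains, per the anchor/co-capture/β rules.

    The proximal anchor fragment (first fragment for cap factors, last for
    PAB1) is retained iff the state includes the factor; for a closed
    molecule the opposite-end anchor is retained with probability
    ``co_capture_eff``; every other fragment independently with
    ``background``.
    """
    n = len(fragments)
    cap_side = factor in CAP_FACTORS
    anchor = 0 if cap_side else n - 1
    distal = n - 1 if cap_side else 0
    engaged = state in ((CLOSED, CAP_ONLY) if cap_side else (CLOSED, TAIL_ONLY))

    kept = []
    for i in range(n):
        if engaged and i == anchor:
            kept.append(True)
        elif state == CLOSED and i == distal:
            kept.append(bool(rng.random() < co_capture_eff))
        else:
            kept.append(bool(rng.random() < background))
    return kept


# ---------------------------------------------------------------------------
# analytic oracle


def expected_enrichment(
    cut_rate: float,
    length: float,
    start: float,
    end: float,
    factor: str,
    p_closed: float,
    p_cap_only: float,
    p_tail_only: float,
    co_capture_eff: float,
    background: float,
) -> float:
    """Exact expected IP/Input ratio for one amplicon.

    With Poisson(λ) cuts, counts on disjoint intervals are independent and
    P(no cut in an interval of length L) = exp(-λL). Writing

        S   = exp(-λ(end-start))      amplicon survives,
        A5  = exp(-λ·end)             amplicon sits on the 5'-end fragment,
        A3  = exp(-λ(length-start))   amplicon sits on the 3'-end fragment,
        A53 = exp(-λ·length)          no cut at all (both at once),

    the probability that the amplicon's fragment is retained in a cap-factor
    IP decomposes over molecule states (anchor retained with probability 1,
    closed-state distal anchor with probability c, everything else with β;
    the A53 overlap is counted once, in the anchor term):

        P_IP = p_closed  · [A5 + c(A3 - A53) + β(S - A5 - A3 + A53)]
             + p_cap_only· [A5 + β(S - A5)]
             + (p_tail_only + p_free) · βS

    (swap A5 ↔ A3 and cap_only ↔ tail_only for a PAB1 IP). The input
    channel retains every fragment, so P_input = S and the expected
    enrichment is P_IP / S.
    """
    lam = cut_rate
    p_free = 1.0 - p_closed - p_cap_only - p_tail_only
    S = math.exp(-lam * (end - start))
    A5 = math.exp(-lam * end)
    A3 = math.exp(-lam * (length - start))
    A53 = math.exp(-lam * length)
    c, beta = co_capture_eff, background

    closed_term = c * 0.0
    if factor in CAP_FACTORS:
        closed_term = A5 + c * (A3 - A53) + beta * (S - A5 - A3 + A53)
        own_term = A5 + beta * (S - A5)
        other_open = p_tail_only
        own_open = p_cap_only
    elif factor in TAIL_FACTORS:
        closed_term = A3 + c * (A5 - A53) + beta * (S - A5 - A3 + A53)
        own_term = A3 + beta * (S - A3)
        other_open = p_cap_only
        own_open = p_tail_only
    else:
        raise ValueError(f"unknown factor '{factor}'")

    p_ip = p_closed * closed_term + own_open * own_term + (other_open + p_free) * beta * S
    return p_ip / S


def expected_profile(config: SimulationConfig, transcript_id: str, factor: str,
                     condition: str | None = None) -> pd.DataFrame:
    """Closed-form expected IP/Input ratio for every assay of a transcript."""
    cond = next(
        (c for c in config.conditions if condition is None or c.name == condition),
        None,
    )
    if cond is None:
        raise ValueError(f"unknown condition '{condition}'")
    tr0 = next((t for t in config.transcripts if t.transcript_id == transcript_id), None)
    if tr0 is None:
        raise ValueError(f"unknown transcript '{transcript_id}'")
    tr = config.transcript_in(tr0, cond)
    rows = []
    for aid, s, e, cls in config.assays_of(tr):
        exp_r = expected_enrichment(
            config.cut_rate_for(cond), tr.length, s, e, factor,
            tr.p_closed, tr.p_cap_only, tr.p_tail_only,
            config.co_capture_for(factor, cond), config.background_for(cond),
        )
        rows.append((transcript_id, cond.name, factor, aid, cls, exp_r))
    return pd.DataFrame(
        rows, columns=["transcript_id", "condition", "factor", "assay_id", "region_class", "expected"]
    )


# ---------------------------------------------------------------------------
# vectorized molecule population → per-assay counts


def simulate_counts(
    tr: TranscriptSim,
    assays: tuple,
    factor: str,
    cut_rate: float,
    co_capture_eff: float,
    background: float,
    n_molecules: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """IP and input amplifiable counts per assay for one molecule population.

    Vectorized equivalent of running :func:`fragment`, :func:`assign_state`
    and :func:`capture` molecule by molecule (agreement is tested). Only
    three per-assay events matter: amplicon survival (no cut inside it) and
    co-location with either end fragment (no cut between the amplicon and
    that end). The closed-state distal co-capture coin is drawn once per
    molecule (it is a property of the bridged complex, shared by every
    amplicon on the distal fragment); background coins are per assay.
    """
    n = n_molecules
    k = rng.poisson(cut_rate * tr.length, n)
    cuts = rng.uniform(0.0, tr.length, int(k.sum()))
    mol = np.repeat(np.arange(n), k)

    u = rng.random(n)
    p1, p2, p3 = tr.p_closed, tr.p_closed + tr.p_cap_only, tr.p_closed + tr.p_cap_only + tr.p_tail_only
    state = np.select([u < p1, u < p2, u < p3], [CLOSED, CAP_ONLY, TAIL_ONLY], default=FREE)
    coin_c = rng.random(n) < co_capture_eff

    cap_side = factor in CAP_FACTORS
    engaged_states = (CLOSED, CAP_ONLY) if cap_side else (CLOSED, TAIL_ONLY)

    ip_counts = np.empty(len(assays), dtype=np.int64)
    input_counts = np.empty(len(assays), dtype=np.int64)
    for j, (_aid, s, e, _cls) in enumerate(assays):
        below_s = np.bincount(mol[cuts < s], minlength=n)
        below_e = np.bincount(mol[cuts < e], minlength=n)
        survive = (below_e - below_s) == 0
        co5 = below_e == 0
        co3 = below_s == k
        on_anchor, on_distal = (co5, co3) if cap_side else (co3, co5)

        anchored = np.isin(state, engaged_states) & on_anchor
        distal = (state == CLOSED) & on_distal & ~anchored
        other = ~anchored & ~distal
        bg = rng.random(n) < background
        captured = survive & (anchored | (distal & coin_c) | (other & bg))

        ip_counts[j] = int(captured.sum())
        input_counts[j] = int(survive.sum())
    return ip_counts, input_counts


def count_enrichment_table(config: SimulationConfig, seed: int) -> pd.DataFrame:
    """Raw IP/Input enrichment computed directly from simulated counts.

    The noise-free fast path: skips the qPCR read-out (Ct noise, efficiency
    estimation) and returns the count-level enrichment table in the same
    tidy layout the analysis pipeline produces, for calibration experiments
    that need many replications.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    rows = []
    for cond in config.conditions:
        for bio_rep in range(1, config.n_bio + 1):
            for factor in config.factors:
                for tr0 in config.transcripts:
                    tr = config.transcript_in(tr0, cond)
                    assays = config.assays_of(tr)
                    ip, inp = simulate_counts(
                        tr, assays, factor,
                        config.cut_rate_for(cond),
                        config.co_capture_for(factor, cond),
                        config.background_for(cond),
                        config.n_molecules, rng,
                    )
                    for (aid, _s, _e, cls), n_ip, n_in in zip(assays, ip, inp):
                        raw = n_ip / n_in if n_in > 0 else np.nan
                        rows.append(
                            (tr.transcript_id, factor, cond.name, bio_rep, aid, cls, raw, np.nan)
                        )
    return pd.DataFrame(
        rows,
        columns=["transcript_id", "factor", "condition", "bio_rep",
                 "assay_id", "region_class", "raw", "se_log"],
    )


def simulate_indices(config: SimulationConfig, factor: str, seed: int) -> pd.DataFrame:
    """Per-replicate closed-loop indices straight from simulated counts.

    Simulates only the two end amplicons of each transcript (the index is
    invariant to normalization, so internal amplicons and the qPCR read-out
    do not affect it) and returns one row per transcript x condition x
    biological replicate. This is the cheap path for experiments that need
    hundreds of replications, e.g. calibrating the condition-comparison
    test under its null.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    cap_side = factor in CAP_FACTORS
    rows = []
    for cond in config.conditions:
        for bio_rep in range(1, config.n_bio + 1):
            for tr0 in config.transcripts:
                tr = config.transcript_in(tr0, cond)
                ends = tuple(
                    a for a in config.assays_of(tr) if a[3] in ("five_prime", "three_prime")
                )
                ip, inp = simulate_counts(
                    tr, ends, factor,
                    config.cut_rate_for(cond),
                    config.co_capture_for(factor, cond),
                    config.background_for(cond),
                    config.n_molecules, rng,
                )
                by_class = {cls: (n_ip, n_in) for (_, _, _, cls), n_ip, n_in in zip(ends, ip, inp)}
                prox_cls = "five_prime" if cap_side else "three_prime"
                dist_cls = "three_prime" if cap_side else "five_prime"
                (ip_p, in_p), (ip_d, in_d) = by_class[prox_cls], by_class[dist_cls]
                if min(ip_p, in_p, ip_d, in_d) == 0:
                    index = np.nan
                else:
                    index = (ip_d / in_d) / (ip_p / in_p)
                rows.append((tr.transcript_id, factor, cond.name, bio_rep, index))
    return pd.DataFrame(rows, columns=["transcript_id", "factor", "condition", "bio_rep", "index"])


# ---------------------------------------------------------------------------
# full dataset generation (Ct tables in the interchange formats)


def generate_ct_dataset(config: SimulationConfig, seed: int) -> dict[str, pd.DataFrame]:
    """Simulate the full experiment and emit the five interchange tables.

    Returns a dict of DataFrames: ``ct`` (long-format Ct table), ``dilution``
    (standard curves), ``assays`` (amplicon annotations), ``samples``
    (sample sheet with IP↔input pairing), ``truth`` (per transcript x
    condition generative parameters and true closed fractions) and
    ``expected`` (closed-form expected enrichment per assay x factor).
    Identical (config, seed) yields identical tables.
    """
    config.validate()
    rng = np.random.default_rng(seed)

    # per-assay chemistry, drawn once per dataset
    assay_rows = []
    for tr in config.transcripts:
        for aid, s, e, cls in config.assays_of(tr):
            assay_rows.append((aid, tr.transcript_id, s, e, cls, tr.length))
    assays_df = pd.DataFrame(
        assay_rows,
        columns=["assay_id", "transcript_id", "start", "end", "region_class", "transcript_length"],
    )
    lo_e, hi_e = config.efficiency_range
    lo_i, hi_i = config.intercept_range
    eff = {aid: rng.uniform(lo_e, hi_e) for aid in assays_df["assay_id"]}
    intercept = {aid: rng.uniform(lo_i, hi_i) for aid in assays_df["assay_id"]}

    def cts_for(aid: str, count: float, n_reps: int) -> list[float]:
        if count < 1:
            return [np.nan] * n_reps
        base = intercept[aid] - math.log(count) / math.log(eff[aid])
        noise = rng.normal(0.0, config.ct_noise_sd, n_reps) if config.ct_noise_sd > 0 else np.zeros(n_reps)
        return list(base + noise)

    sample_rows, ct_rows = [], []
    for cond in config.conditions:
        for bio_rep in range(1, config.n_bio + 1):
            for factor in config.factors:
                sid_ip = f"{factor}_{cond.name}_r{bio_rep}_IP"
                sid_in = f"{factor}_{cond.name}_r{bio_rep}_input"
                sample_rows.append((sid_ip, factor, "IP", cond.name, bio_rep, sid_in))
                sample_rows.append((sid_in, factor, "input", cond.name, bio_rep, ""))
                for tr0 in config.transcripts:
                    tr = config.transcript_in(tr0, cond)
                    assays = config.assays_of(tr)
                    ip, inp = simulate_counts(
                        tr, assays, factor,
                        config.cut_rate_for(cond),
                        config.co_capture_for(factor, cond),
                        config.background_for(cond),
                        config.n_molecules, rng,
                    )
                    for (aid, _s, _e, _cls), n_ip, n_in in zip(assays, ip, inp):
                        for rep, ct in enumerate(cts_for(aid, n_ip, config.n_tech), start=1):
                            ct_rows.append((sid_ip, aid, rep, ct))
                        for rep, ct in enumerate(cts_for(aid, n_in, config.n_tech), start=1):
                            ct_rows.append((sid_in, aid, rep, ct))

    ct_df = pd.DataFrame(ct_rows, columns=["sample_id", "assay_id", "tech_rep", "ct"])
    ct_df["flagged"] = False
    samples_df = pd.DataFrame(
        sample_rows, columns=["sample_id", "factor", "fraction", "condition", "bio_rep", "input_pair"]
    )

    dil_rows = []
    for aid in assays_df["assay_id"]:
        base_count = float(config.n_molecules)
        for d in config.dilution_levels:
            for rep, ct in enumerate(cts_for(aid, base_count * d, config.n_tech), start=1):
                dil_rows.append((aid, d, rep, ct))
    dilution_df = pd.DataFrame(dil_rows, columns=["assay_id", "dilution", "tech_rep", "ct"])

    truth_rows, expected_parts = [], []
    for cond in config.conditions:
        for tr0 in config.transcripts:
            tr = config.transcript_in(tr0, cond)
            truth_rows.append(
                (
                    tr.transcript_id, cond.name, tr.length,
                    tr.p_closed, tr.p_cap_only, tr.p_tail_only, tr.p_free,
                    tr.closed_fraction_cap, tr.closed_fraction_tail,
                    config.cut_rate_for(cond), config.background_for(cond),
                    *(config.co_capture_for(f, cond) for f in config.factors),
                    config.n_molecules,
                )
            )
            for factor in config.factors:
                expected_parts.append(expected_profile(config, tr.transcript_id, factor, cond.name))
    truth_df = pd.DataFrame(
        truth_rows,
        columns=[
            "transcript_id", "condition", "length",
            "p_closed", "p_cap_only", "p_tail_only", "p_free",
            "closed_fraction_cap", "closed_fraction_tail",
            "cut_rate", "background",
            *(f"co_capture_{f}" for f in config.factors),
            "n_molecules",
        ],
    )
    expected_df = pd.concat(expected_parts, ignore_index=True)

    return {
        "ct": ct_df,
        "dilution": dilution_df,
        "assays": assays_df,
        "samples": samples_df,
        "truth": truth_df,
        "expected": expected_df,
    }


# ---------------------------------------------------------------------------
# config (de)serialization for the CLI


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a SimulationConfig from a plain dict (YAML-friendly).

    Transcripts may be given explicitly (``transcript_id, length`` plus
    either the three state probabilities or a ``closed_fraction``), or via
    ``n_transcripts`` to use the default study design.
    """
    d = dict(d)
    if "transcripts" in d:
        trs = []
        for t in d.pop("transcripts"):
            if "closed_fraction" in t:
                trs.append(
                    TranscriptSim.from_closed_fraction(
                        t["transcript_id"], int(t["length"]), float(t["closed_fraction"]),
                        cap_engaged=float(t.get("cap_engaged", 0.5)),
                        p_tail_only=float(t.get("p_tail_only", 0.3)),
                    )
                )
            else:
                trs.append(
                    TranscriptSim(
                        transcript_id=t["transcript_id"], length=int(t["length"]),
                        p_closed=float(t["p_closed"]), p_cap_only=float(t["p_cap_only"]),
                        p_tail_only=float(t["p_tail_only"]),
                        assays=tuple(tuple(a) for a in t["assays"]) if "assays" in t else None,
                    )
                )
        transcripts = tuple(trs)
    else:
        transcripts = default_config(int(d.pop("n_transcripts", 16))).transcripts

    conditions = tuple(
        Condition(
            name=c.get("name", "steady"),
            cut_rate=c.get("cut_rate"),
            co_capture_eff=c.get("co_capture_eff"),
            background=c.get("background"),
            p_closed_scale=float(c.get("p_closed_scale", 1.0)),
        )
        for c in d.pop("conditions", [{"name": "steady"}])
    )
    kwargs = {}
    for key in ("cut_rate", "co_capture_eff", "background", "n_molecules", "ct_noise_sd",
                "n_tech", "n_bio"):
        if key in d:
            kwargs[key] = d.pop(key)
    if "factors" in d:
        kwargs["factors"] = tuple(d.pop("factors"))
    for key in ("efficiency_range", "intercept_range", "dilution_levels"):
        if key in d:
            kwargs[key] = tuple(d.pop(key))
    if d:
        raise ValueError(f"unknown simulation config key(s): {sorted(d)}")
    cfg = SimulationConfig(transcripts=transcripts, conditions=conditions, **kwargs)
    cfg.validate()
    return cfg


def config_to_dict(config: SimulationConfig) -> dict:
    """Plain-dict snapshot of a config (for the run manifest)."""
    return {
        "transcripts": [
            {
                "transcript_id": t.transcript_id, "length": t.length,
                "p_closed": t.p_closed, "p_cap_only": t.p_cap_only, "p_tail_only": t.p_tail_only,
            }
            for t in config.transcripts
        ],
        "factors": list(config.factors),
        "conditions": [
            {
                "name": c.name, "cut_rate": c.cut_rate, "co_capture_eff": c.co_capture_eff,
                "background": c.background, "p_closed_scale": c.p_closed_scale,
            }
            for c in config.conditions
        ],
        "cut_rate": config.cut_rate,
        "co_capture_eff": config.co_capture_eff,
        "background": config.background,
        "n_molecules": config.n_molecules,
        "ct_noise_sd": config.ct_noise_sd,
        "n_tech": config.n_tech,
        "n_bio": config.n_bio,
        "efficiency_range": list(config.efficiency_range),
        "intercept_range": list(config.intercept_range),
        "dilution_levels": list(config.dilution_levels),
    }
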