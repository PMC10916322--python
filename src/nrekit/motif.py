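"""Motif discovery and scanning on trimmed NRE segments.

Discovery uses a ZOOPS (zero-or-one occurrence per sequence) mixture model
fitted by expectation-maximization from k-mer-seeded starts; candidate
models are ranked by a log-likelihood-ratio statistic with a chi-square
approximate p-value.  Scanning scores every offset of a segment against a
position weight matrix (log-odds, bits) and converts scores to exact
p-values computed by dynamic programming over the integer-discretized score
distribution of a random background word — the same contract as FIMO-style
scanners.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import chi2

from .model import AMINO_ACIDS, AA_INDEX, DEGENERATE, NRESegment, expand

DEGENERATE_PAIRS = {frozenset(v): k for k, v in DEGENERATE.items() if len(v) == 2}


# --- sequence encoding ------------------------------------------------------


def seq_matrix(seq: str) -> np.ndarray:
    """(L, 20) indicator matrix; degenerate letters spread fractionally."""
    X = np.zeros((len(seq), 20))
    for i, c in enumerate(seq):
        members = expand(c)
        X[i, [AA_INDEX[m] for m in members]] = 1.0 / len(members)
    return X


def build_background(segments: list[NRESegment]) -> np.ndarray:
    """Letter frequencies over the corpus with +1 pseudocount per letter.

    Degenerate letters distribute fractionally over their expansion sets, so
    a 'B' adds half a count to each of D and N.
    """
    if not segments:
        raise ValueError("no segments")
    counts = np.ones(20)
    for seg in segments:
        counts += seq_matrix(seg.sequence).sum(axis=0)
    return counts / counts.sum()


# --- PWM model --------------------------------------------------------------


@dataclass
class MotifModel:
    """A width-w count/log-odds motif model.

    ``counts`` holds (possibly fractional) site counts per column;
    ``log_odds`` is base-2 versus ``background``.  ``consensus`` takes the
    argmax letter per column, degenerate (B/Z/J) when the runner-up is
    within 0.8x of the maximum and the pair has a degenerate code.
    """

    id: str
    width: int
    counts: np.ndarray
    log_odds: np.ndarray
    background: np.ndarray
    consensus: str
    nsites: float = 0.0
    gamma: float = 0.0
    llr: float = 0.0
    p_value: float = 1.0
    _pv: "PValueTable | None" = field(default=None, repr=False, compare=False)

    def pvalue_table(self, resolution: float = 1e-3) -> "PValueTable":
        if self._pv is None or self._pv.resolution != resolution:
            self._pv = pwm_pvalue_table(self, self.background, resolution)
        return self._pv


def _consensus_from_freqs(freqs: np.ndarray) -> str:
    letters = []
    for col in freqs:
        order = np.argsort(col)[::-1]
        top, second = order[0], order[1]
        if col[second] >= 0.8 * col[top]:
            code = DEGENERATE_PAIRS.get(frozenset({AMINO_ACIDS[top], AMINO_ACIDS[second]}))
            if code:
                letters.append(code)
                continue
        letters.append(AMINO_ACIDS[top])
    return "".join(letters)


def build_pwm(
    site_sequences: list[str],
    background: np.ndarray,
    pseudocount: float = 0.1,
    motif_id: str = "motif",
) -> MotifModel:
    """Count matrix -> frequency -> base-2 log-odds PWM.

    The per-column pseudocount mass (``pseudocount`` total) is spread in
    proportion to the background, keeping log-odds finite.  Degenerate
    letters in sites contribute fractionally over their expansion sets.
    """
    if len(site_sequences) < 2:
        raise ValueError("need at least two sites")
    widths = {len(s) for s in site_sequences}
    if len(widths) != 1:
        raise ValueError(f"sites have mixed widths: {sorted(widths)}")
    w = widths.pop()
    counts = np.zeros((w, 20))
    for s in site_sequences:
        counts += seq_matrix(s)
    return pwm_from_counts(counts, background, pseudocount, motif_id)


def pwm_from_counts(
    counts: np.ndarray,
    background: np.ndarray,
    pseudocount: float = 0.1,
    motif_id: str = "motif",
    gamma: float = 0.0,
    llr: float = 0.0,
    p_value: float = 1.0,
) -> MotifModel:
    n = counts.sum(axis=1)
    freqs = (counts + pseudocount * background) / (n[:, None] + pseudocount)
    log_odds = np.log2(freqs / background)
    return MotifModel(
        id=motif_id,
        width=counts.shape[0],
        counts=counts,
        log_odds=log_odds,
        background=background.copy(),
        consensus=_consensus_from_freqs(freqs),
        nsites=float(n.mean()),
        gamma=gamma,
        llr=llr,
        p_value=p_value,
    )


# --- exact p-values by dynamic programming ----------------------------------


@dataclass
class PValueTable:
    """Exact tail distribution of the discretized PWM score.

    Scores are integerized per cell to the nearest multiple of
    ``resolution`` (bits); the tail of the total over a random i.i.d.
    background word is then computed by exact convolution, so
    ``p(score_int(word))`` equals brute-force enumeration for any word,
    with per-word score distortion at most width * resolution / 2.
    """

    int_scores: np.ndarray  # width x 20, int64
    min_total: int
    tail: np.ndarray        # tail[k] = P(total >= min_total + k)
    resolution: float

    def score_int(self, window: np.ndarray) -> int:
        """Integer score of a (w, 20) indicator window (fractional rows for
        degenerate letters score as the expansion mean)."""
        return int(round(float((window * self.int_scores).sum())))

    def pvalue_int(self, s: int) -> float:
        k = s - self.min_total
        if k < 0:
            return 1.0
        if k >= len(self.tail):
            return float(self.tail[-1])
        return float(self.tail[k])

    def pvalue(self, score_bits: float) -> float:
        return self.pvalue_int(int(round(score_bits / self.resolution)))


def score_tail_table(
    log_odds: np.ndarray, background: np.ndarray, resolution: float = 1e-3
) -> PValueTable:
    """Exact tail of the discretized score over any alphabet size.

    Works column by column: the distribution of the integer total is the
    convolution of the per-column score distributions under the background.
    """
    if log_odds.shape[0] == 0:
        raise ValueError("zero-width motif")
    if not np.all(np.isfinite(log_odds)):
        raise ValueError("log-odds must be finite")
    ints = np.round(log_odds / resolution).astype(np.int64)
    min_total = int(ints.min(axis=1).sum())
    max_total = int(ints.max(axis=1).sum())
    dist = np.zeros(1)
    dist[0] = 1.0
    for k in range(ints.shape[0]):
        col = ints[k] - ints[k].min()
        new = np.zeros(len(dist) + int(col.max()))
        for a in range(len(background)):
            new[col[a] : col[a] + len(dist)] += background[a] * dist
        dist = new
    assert len(dist) == max_total - min_total + 1
    tail = np.cumsum(dist[::-1])[::-1]
    tail = np.minimum(tail, 1.0)  # guard rounding above 1
    return PValueTable(int_scores=ints, min_total=min_total, tail=tail, resolution=resolution)


def pwm_pvalue_table(
    motif: MotifModel, background: np.ndarray, resolution: float = 1e-3
) -> PValueTable:
    return score_tail_table(motif.log_odds, background, resolution)


# --- scanning ---------------------------------------------------------------


@dataclass(frozen=True)
class MotifMatch:
    """A located motif occurrence within an NRE segment (1-based inclusive)."""

    motif_id: str
    protein_id: str
    start: int
    end: int
    score: float  # bits
    p_value: float


def scan(
    motif: MotifModel,
    segment: NRESegment,
    p_threshold: float = 0.001,
    resolution: float = 1e-3,
) -> list[MotifMatch]:
    """Score every offset of the segment; report p <= threshold occurrences.

    Overlapping matches of the same motif collapse to the best-p one per
    overlap group, ties resolved leftmost.
    """
    w = motif.width
    L = segment.length
    if L < w:
        return []
    pv = motif.pvalue_table(resolution)
    X = seq_matrix(segment.sequence)
    V = X @ pv.int_scores.T  # (L, w): contribution of position i as column k
    m = L - w + 1
    totals = np.zeros(m)
    for k in range(w):
        totals += V[k : k + m, k]
    raw = []
    for j in range(m):
        s = int(round(totals[j]))
        p = pv.pvalue_int(s)
        if p <= p_threshold:
            raw.append(
                MotifMatch(
                    motif_id=motif.id,
                    protein_id=segment.protein_id,
                    start=j + 1,
                    end=j + w,
                    score=s * resolution,
                    p_value=p,
                )
            )
    return _resolve_overlaps(raw)


def _resolve_overlaps(matches: list[MotifMatch]) -> list[MotifMatch]:
    if not matches:
        return []
    matches = sorted(matches, key=lambda mm: mm.start)
    out = []
    group = [matches[0]]
    for mm in matches[1:]:
        if mm.start <= group[-1].end:
            group.append(mm)
        else:
            out.append(min(group, key=lambda g: (g.p_value, g.start)))
            group = [mm]
    out.append(min(group, key=lambda g: (g.p_value, g.start)))
    return out


def scan_all(
    motifs: list[MotifModel],
    segments: list[NRESegment],
    p_threshold: float = 0.001,
) -> list[MotifMatch]:
    """Scan every motif against every segment; order-independent output."""
    out = []
    for motif in motifs:
        for seg in sorted(segments, key=lambda s: (s.protein_id, s.start)):
            out.extend(scan(motif, seg, p_threshold))
    return out


# --- ZOOPS expectation-maximization discovery -------------------------------


class ZoopsDiscovery:
    """ZOOPS motif discovery by expectation-maximization.

    Model: each sequence carries at most one motif site; with probability
    ``gamma`` a site sits at one of its L-w+1 offsets uniformly, otherwise
    the sequence is pure background.  The E-step computes per-offset
    posterior occurrence probabilities; the M-step re-estimates the PWM
    (with a background-proportional Dirichlet pseudocount) and the
    occurrence prior.  The penalized (MAP) objective is asserted
    non-decreasing at every iteration.  Starts are seeded from k-mers
    sampled from the data; everything is deterministic given ``seed``.

    After :meth:`fit`, ``motifs_`` holds the discovered models ranked by
    significance.
    """

    def __init__(
        self,
        width_range: tuple[int, int] = (10, 44),
        n_motifs: int = 1,
        p_threshold: float = 0.005,
        seed: int = 0,
        max_iter: int = 200,
        tol: float = 1e-6,
        n_starts: int = 8,
        pseudocount: float = 0.1,
        width_step: int = 1,
    ):
        self.width_range = width_range
        self.n_motifs = n_motifs
        self.p_threshold = p_threshold
        self.seed = seed
        self.max_iter = max_iter
        self.tol = tol
        self.n_starts = n_starts
        self.pseudocount = pseudocount
        self.width_step = width_step

    # -- EM internals --

    @staticmethod
    def _window_scores(X: np.ndarray, log_ratio: np.ndarray) -> np.ndarray:
        """Log-likelihood ratios of every width-w window of one sequence."""
        w = log_ratio.shape[0]
        L = X.shape[0]
        m = L - w + 1
        V = X @ log_ratio.T
        s = np.zeros(m)
        for k in range(w):
            s += V[k : k + m, k]
        return s

    def _em(self, Xs, log_bg, width, f0, gamma0, erase):
        """Run EM to convergence from one start; returns (J, f, gamma, z_list)."""
        alpha = self.pseudocount * np.exp(log_bg)  # Dirichlet pseudocounts
        f, gamma = f0, gamma0
        J_prev = -np.inf
        z_list = None
        for _ in range(self.max_iter):
            log_ratio = np.log(f) - log_bg[None, :]
            # E-step
            J = 0.0
            z_list = []
            gamma_num = 0.0
            n_contributing = 0
            for X, er in zip(Xs, erase):
                m = X.shape[0] - width + 1
                if m < 1:
                    z_list.append(np.zeros(0))
                    continue
                n_contributing += 1
                s = self._window_scores(X, log_ratio)
                if er is not None:
                    s = s + er  # log erasure weight per window
                log_terms = np.log(gamma / m) + s
                log_denom = logsumexp(np.append(log_terms, np.log1p(-gamma)))
                z = np.exp(log_terms - log_denom)
                z_list.append(z)
                J += log_denom
                gamma_num += z.sum()
            exp_counts = np.zeros_like(f)
            for X, z in zip(Xs, z_list):
                m = len(z)
                if m == 0:
                    continue
                for k in range(width):
                    exp_counts[k] += z @ X[k : k + m]
            J += float((alpha[None, :] * np.log(f)).sum())
            # monotone up to accumulated float error in logsumexp sums
            if not (J >= J_prev - 1e-7 * max(1.0, abs(J_prev))):
                raise AssertionError(f"EM objective decreased: {J_prev} -> {J}")
            converged = J - J_prev < self.tol
            J_prev = J
            # M-step
            f = exp_counts + alpha[None, :]
            f = f / f.sum(axis=1, keepdims=True)
            gamma = float(np.clip(gamma_num / max(n_contributing, 1), 1e-4, 1 - 1e-4))
            if converged:
                break
        return J_prev, f, gamma, z_list

    def _shifted_start(self, Xs, z_list, width, shift, bg):
        """PWM seeded from converged posteriors with windows moved by
        ``shift`` columns; used to escape alignment local optima."""
        counts = np.zeros((width, 20))
        for X, z in zip(Xs, z_list):
            m = len(z)
            if m == 0:
                continue
            a = max(0, -shift)
            b = m - max(0, shift)
            if b <= a:
                continue
            z_sub = z[a:b]
            for k in range(width):
                counts[k] += z_sub @ X[a + shift + k : a + shift + k + (b - a)]
        if counts.sum() < 1.0:
            return None
        f = counts + self.pseudocount * bg[None, :]
        return f / f.sum(axis=1, keepdims=True)

    def _null_objective(self, Xs, log_bg, width, f, gamma):
        """Penalized objective of the background-only model (gamma -> 0),
        sharing the pseudocount prior term so LLR compares like with like."""
        alpha = self.pseudocount * np.exp(log_bg)
        return float((alpha[None, :] * np.log(f)).sum())

    # -- public API --

    def fit(self, segments: list[NRESegment]) -> "ZoopsDiscovery":
        if len(segments) < 10:
            raise ValueError("need at least 10 segments for discovery")
        rng = np.random.default_rng(self.seed)
        segments = sorted(segments, key=lambda s: (s.protein_id, s.start))
        Xs = [seq_matrix(s.sequence) for s in segments]
        bg = build_background(segments)
        log_bg = np.log(bg)
        lo, hi = self.width_range
        widths = [w for w in range(lo, hi + 1, self.width_step)
                  if any(X.shape[0] >= w for X in Xs)]
        erase_w = [np.zeros(X.shape[0]) for X in Xs]  # log per-position erasure
        found: list[MotifModel] = []
        for imotif in range(self.n_motifs):
            best = None  # (p, -llr, width, f, gamma, z_list)
            for width in widths:
                erase = []
                for X, e in zip(Xs, erase_w):
                    m = X.shape[0] - width + 1
                    if m < 1:
                        erase.append(None)
                        continue
                    c = np.cumsum(np.concatenate(([0.0], e)))
                    erase.append(c[width:] - c[:-width])
                starts = self._seed_starts(Xs, bg, width, rng)
                wbest = None  # (J, f, gamma, z_list)
                for f0 in starts:
                    J, f, gamma, z_list = self._em(Xs, log_bg, width, f0, 0.3, erase)
                    if wbest is None or J > wbest[0]:
                        wbest = (J, f, gamma, z_list)
                # column-shift refinement: escape off-by-k alignment optima
                J, f, gamma, z_list = wbest
                for _ in range(8):
                    improved = False
                    for shift in (-3, -2, -1, 1, 2, 3):
                        f0 = self._shifted_start(Xs, z_list, width, shift, bg)
                        if f0 is None:
                            continue
                        J2, f2, g2, z2 = self._em(Xs, log_bg, width, f0, gamma, erase)
                        if J2 > J + 1e-6:
                            J, f, gamma, z_list = J2, f2, g2, z2
                            improved = True
                            break
                    if not improved:
                        break
                J0 = self._null_objective(Xs, log_bg, width, f, gamma)
                llr = 2.0 * max(J - J0, 0.0)
                df = width * 19 + 1
                p = float(chi2.sf(llr, df))
                key = (p, -llr)
                if best is None or key < best[0]:
                    best = (key, width, f, gamma, z_list, llr, p)
            if best is None:
                break
            _, width, f, gamma, z_list, llr, p = best
            if p > self.p_threshold:
                break
            counts = np.zeros_like(f)
            total_z = 0.0
            for X, z in zip(Xs, z_list):
                m = len(z)
                if m == 0:
                    continue
                total_z += z.sum()
                for k in range(width):
                    counts[k] += z @ X[k : k + m]
            model = pwm_from_counts(
                counts, bg, self.pseudocount,
                motif_id=f"motif_{imotif + 1}", gamma=gamma, llr=llr, p_value=p,
            )
            found.append(model)
            # probabilistic masking: positions under probable sites are damped
            for ei, z in zip(erase_w, z_list):
                m = len(z)
                for j in range(m):
                    if z[j] > 1e-6:
                        ei[j : j + width] += np.log1p(-min(z[j], 1 - 1e-6))
        self.motifs_ = found
        self.background_ = bg
        self.segments_ = segments
        return self

    def _seed_starts(self, Xs, bg, width, rng) -> list[np.ndarray]:
        """PWM starts seeded from k-mers sampled from the data."""
        eligible = [i for i, X in enumerate(Xs) if X.shape[0] >= width]
        starts = []
        for _ in range(self.n_starts):
            i = eligible[rng.integers(len(eligible))]
            X = Xs[i]
            j = int(rng.integers(X.shape[0] - width + 1))
            window = X[j : j + width]
            f0 = 0.6 * window + 0.4 * bg[None, :]
            f0 = f0 / f0.sum(axis=1, keepdims=True)
            starts.append(f0)
        return starts

    def predicted_sites(self, motif_index: int = 0, min_posterior: float = 0.5):
        """MAP site per sequence (offset of the posterior mode) for a motif.

        Re-runs one E-step of the fitted model; returns a list of
        (protein_id, start) for sequences whose best posterior exceeds
        ``min_posterior``.
        """
        model = self.motifs_[motif_index]
        f = (model.counts + self.pseudocount * self.background_[None, :])
        f = f / f.sum(axis=1, keepdims=True)
        log_bg = np.log(self.background_)
        log_ratio = np.log(f) - log_bg[None, :]
        out = []
        for seg in self.segments_:
            X = seq_matrix(seg.sequence)
            m = X.shape[0] - model.width + 1
            if m < 1:
                continue
            s = self._window_scores(X, log_ratio)
            log_terms = np.log(model.gamma / m) + s
            log_denom = logsumexp(np.append(log_terms, np.log1p(-model.gamma)))
            z = np.exp(log_terms - log_denom)
            j = int(np.argmax(z))
            if z[j] >= min_posterior:
                out.append((seg.protein_id, j + 1))
        return out


def discover_zoops(
    segments: list[NRESegment],
    width_range: tuple[int, int] = (10, 44),
    n_motifs: int = 1,
    p_threshold: float = 0.005,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
    **kwargs,
) -> list[MotifModel]:
    """Functional wrapper over :class:`ZoopsDiscovery`."""
    disc = ZoopsDiscovery(
        width_range=width_range,
        n_motifs=n_motifs,
        p_threshold=p_threshold,
        seed=seed,
        max_iter=max_iter,
        tol=tol,
        **kwargs,
    )
    disc.fit(segments)
    return disc.motifs_


# --- MEME minimal text format ----------------------------------------------


def write_meme(motifs: list[MotifModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= " + AMINO_ACIDS + "\n\n")
        if motifs:
            bg = motifs[0].background
            fh.write("Background letter frequencies\n")
            fh.write(" ".join(f"{a} {p:.6f}" for a, p in zip(AMINO_ACIDS, bg)) + "\n\n")
        for m in motifs:
            n = m.counts.sum(axis=1)
            freqs = (m.counts + 1e-9) / (n[:, None] + 2e-8)
            fh.write(f"MOTIF {m.id} {m.consensus}\n")
            fh.write(
                f"letter-probability matrix: alength= 20 w= {m.width} "
                f"nsites= {max(int(round(m.nsites)), 1)} E= {m.p_value:.3g}\n"
            )
            for row in freqs:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


def read_meme(path) -> list[MotifModel]:
    motifs = []
    bg = np.full(20, 0.05)
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith("Background letter frequencies"):
            toks = lines[i + 1].split()
            bg = np.array([float(toks[k * 2 + 1]) for k in range(20)])
            i += 2
            continue
        if line.startswith("MOTIF"):
            motif_id = line.split()[1]
            i += 1
            while not lines[i].startswith("letter-probability"):
                i += 1
            # parse "alength= 20 w= 12 nsites= 30 E= ..."
            toks = lines[i].replace("letter-probability matrix:", "").split()
            kv = {toks[k].rstrip("="): toks[k + 1] for k in range(0, len(toks) - 1, 2)}
            w = int(kv["w"])
            nsites = int(kv.get("nsites", 20))
            rows = []
            for k in range(w):
                i += 1
                rows.append([float(x) for x in lines[i].split()])
            freqs = np.array(rows)
            counts = freqs * nsites
            motifs.append(pwm_from_counts(counts, bg, motif_id=motif_id))
        i += 1
    return motifs


MATCH_COLUMNS = ["motif_id", "sequence_id", "start", "stop", "score", "p-value", "matched_sequence"]


def matches_to_rows(matches: list[MotifMatch], segments: list[NRESegment]) -> list[dict]:
    """FIMO-style rows (coordinates within the NRE segment)."""
    seq_by_id = {s.protein_id: s.sequence for s in segments}
    rows = []
    for mm in matches:
        rows.append(
            {
                "motif_id": mm.motif_id,
                "sequence_id": mm.protein_id,
                "start": mm.start,
                "stop": mm.end,
                "score": round(mm.score, 4),
                "p-value": f"{mm.p_value:.3g}",
                "matched_sequence": seq_by_id.get(mm.protein_id, "")[mm.start - 1 : mm.end],
            }
        )
    return rows
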