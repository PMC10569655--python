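"""EM-based discovery of the shared ARE motif in intergenic/amplicon DNA.

The autoregulatory response element (ARE) is the palindromic operator bound
by the TetR-family receptor, typically sitting in the intergenic region of a
divergent synthase/receptor pair. This module finds one shared ungapped
motif of width 15-30 across a set of sequences with a ZOOPS
(zero-or-one-occurrence-per-sequence) mixture model fitted by EM, searching
both strands.

Candidate models are seeded from the subsequences of the input: every
(strided) w-mer is scored with a fast vectorised best-match screen, and EM
is run to convergence from the top seeds; the best final model is kept, with
ties broken toward the smaller (sequence, offset) seed. The EM objective
(log likelihood plus a Dirichlet log-prior from the pseudocounts) is
recorded every iteration and is non-decreasing.

Significance is an empirical p-value from a dinucleotide-shuffle null
(Altschul-Erickson shuffling preserves dinucleotide composition): the
fraction of shuffled datasets whose best same-width log-likelihood ratio
reaches the observed one. No analytic E-value is computed. Palindromicity
scores how close the PWM is to its own reverse complement.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

_BASES = "ACGT"
_B_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMP_PERM = np.array([3, 2, 1, 0])  # A<->T, C<->G


@dataclass
class MotifModel:
    """A fitted ungapped DNA motif."""

    pwm: np.ndarray  # (width, 4), rows sum to 1
    width: int
    sites: list[tuple[int, int, str]]  # (sequence index, offset, strand)
    llr: float  # log-likelihood ratio vs background-only model
    background: np.ndarray  # (4,)
    significance: float | None = None
    objective_history: list[float] = field(default_factory=list)

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.pwm.argmax(axis=1))

    def to_text(self, path) -> None:
        """Write the motif in a minimal PWM text format."""
        with open(path, "w") as fh:
            fh.write(f"# motif width={self.width} llr={self.llr:.3f} "
                     f"significance={self.significance} consensus={self.consensus()}\n")
            fh.write("# background " +
                     " ".join(f"{b}:{f:.4f}" for b, f in zip(_BASES, self.background)) + "\n")
            fh.write("pos\tA\tC\tG\tT\n")
            for i, row in enumerate(self.pwm):
                fh.write(f"{i}\t" + "\t".join(f"{p:.5f}" for p in row) + "\n")


def _encode(seqs: Sequence[str]) -> list[np.ndarray]:
    out = []
    for s in seqs:
        s = s.upper()
        bad = set(s) - set(_BASES)
        if bad:
            raise ValueError(f"sequence has invalid characters: {sorted(bad)}")
        out.append(np.array([_B_INDEX[c] for c in s], dtype=np.int8))
    return out


def _background(enc: Sequence[np.ndarray]) -> np.ndarray:
    counts = np.bincount(np.concatenate(enc), minlength=4).astype(float) + 1.0
    return counts / counts.sum()


def _revcomp_enc(a: np.ndarray) -> np.ndarray:
    return _COMP_PERM[a[::-1]]


def _window_matrix(enc: Sequence[np.ndarray], w: int,
                   both_strands: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Stack all windows of width w; return (windows, sequence index per window)."""
    wins, owner = [], []
    for i, a in enumerate(enc):
        for arr in ((a, _revcomp_enc(a)) if both_strands else (a,)):
            if len(arr) < w:
                continue
            sw = np.lib.stride_tricks.sliding_window_view(arr, w)
            wins.append(sw)
            owner.append(np.full(len(sw), i))
    return np.concatenate(wins), np.concatenate(owner)


def _screen_seeds(enc: Sequence[np.ndarray], w: int, stride: int,
                  n_keep: int) -> list[tuple[int, int]]:
    """Rank seed w-mers by summed best-match identity across sequences.

    Returns (sequence index, offset) of the best forward-strand seeds.
    """
    all_wins, owner = _window_matrix(enc, w, both_strands=True)
    n_seq = len(enc)
    seed_locs = [(i, off) for i, a in enumerate(enc)
                 for off in range(0, len(a) - w + 1, stride)]
    seeds = np.stack([enc[i][off:off + w] for i, off in seed_locs])
    scores = np.empty(len(seeds))
    chunk = max(1, 2_000_000 // max(1, len(all_wins)))
    for c0 in range(0, len(seeds), chunk):
        block = seeds[c0:c0 + chunk]  # (B, w)
        match = (block[:, None, :] == all_wins[None, :, :]).sum(axis=2)  # (B, n_win)
        best = np.zeros((len(block), n_seq))
        for s in range(n_seq):
            cols = owner == s
            if cols.any():
                best[:, s] = match[:, cols].max(axis=1)
        scores[c0:c0 + chunk] = best.sum(axis=1)
    order = np.argsort(-scores, kind="stable")
    return [seed_locs[int(k)] for k in order[:n_keep]]


def _em_zoops(enc: Sequence[np.ndarray], w: int, init_pwm: np.ndarray,
              background: np.ndarray, site_prior: float = 0.8,
              max_iter: int = 200, tol: float = 1e-6,
              alpha: float = 0.1) -> tuple[np.ndarray, float, list[float],
                                           list[tuple[int, int, str, float]]]:
    """ZOOPS EM on both strands from an initial PWM.

    Returns (pwm, llr, objective history, per-sequence best site with
    posterior). The objective is the observed-data log likelihood ratio plus
    the Dirichlet log-prior term alpha * sum(log pwm); it is non-decreasing.
    """
    pwm = init_pwm.copy()
    # per sequence: integer-coded windows for both strands
    seq_wins: list[tuple[np.ndarray, np.ndarray]] = []
    for a in enc:
        fw = np.lib.stride_tricks.sliding_window_view(a, w)
        rv = np.lib.stride_tricks.sliding_window_view(_revcomp_enc(a), w)
        seq_wins.append((fw, rv))
    log_bg = np.log(background)

    def e_pass(cur_pwm, accumulate: bool):
        log_pwm = np.log(cur_pwm)
        ll = 0.0
        counts = np.full((w, 4), alpha) if accumulate else None
        sites: list[tuple[int, int, str, float]] = []
        for si, (fw, rv) in enumerate(seq_wins):
            P = len(fw)
            lr_parts = []
            for wins in (fw, rv):
                s = np.zeros(len(wins))
                for k in range(w):
                    s += log_pwm[k, wins[:, k]] - log_bg[wins[:, k]]
                lr_parts.append(np.exp(s))
            lr = np.concatenate(lr_parts)  # forward then reverse windows
            mix = (1.0 - site_prior) + site_prior * lr.sum() / (2 * P)
            ll += np.log(mix)
            resp = (site_prior / (2 * P)) * lr / mix  # site responsibilities
            if accumulate:
                for part, wins in zip((resp[:P], resp[P:]), (fw, rv)):
                    for k in range(w):
                        counts[k] += np.bincount(wins[:, k], weights=part, minlength=4)
            j = int(np.argmax(lr))
            strand = "+" if j < P else "-"
            off = j if j < P else len(enc[si]) - w - (j - P)
            sites.append((si, off, strand, float(resp.sum())))
        return ll, counts, sites

    history: list[float] = []
    prev_obj = -np.inf
    for _ in range(max_iter):
        ll, counts, _ = e_pass(pwm, accumulate=True)
        obj = ll + alpha * float(np.log(pwm).sum())
        history.append(obj)
        if obj - prev_obj < tol and len(history) > 1:
            break
        prev_obj = obj
        pwm = counts / counts.sum(axis=1, keepdims=True)
    final_ll, _, sites = e_pass(pwm, accumulate=False)
    return pwm, float(final_ll), history, sites


def _seed_pwm(enc_seq: np.ndarray, off: int, w: int, match_p: float = 0.7) -> np.ndarray:
    pwm = np.full((w, 4), (1.0 - match_p) / 3.0)
    for k in range(w):
        pwm[k, enc_seq[off + k]] = match_p
    return pwm


def _best_model_for_width(enc: Sequence[np.ndarray], w: int, background: np.ndarray,
                          site_prior: float, stride: int, n_refine: int,
                          max_iter: int, tol: float):
    seeds = _screen_seeds(enc, w, stride, n_refine)
    best = None
    for (si, off) in seeds:
        pwm0 = _seed_pwm(enc[si], off, w)
        pwm, llr, hist, sites = _em_zoops(enc, w, pwm0, background, site_prior,
                                          max_iter, tol)
        key = (-llr, si, off)
        if best is None or key < best[0]:
            best = (key, pwm, llr, hist, sites)
    return best


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul-Erickson shuffle preserving exact dinucleotide counts."""
    if len(seq) <= 2:
        return seq
    seq = seq.upper()
    # adjacency lists of the dinucleotide multigraph
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    vertices = list(edges)
    # choose a terminal edge per vertex (except `last`) forming a tree into `last`
    for _ in range(100):
        terminal: dict[str, str] = {}
        for v in vertices:
            if v != last:
                terminal[v] = edges[v][rng.integers(len(edges[v]))]
        # check every vertex reaches `last` via terminal edges
        ok = True
        for v in terminal:
            seen = {v}
            cur = v
            while cur != last:
                cur = terminal.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # fallback: return input unshuffled (degenerate composition)
        return seq
    shuffled_edges: dict[str, list[str]] = {}
    for v in vertices:
        rest = list(edges[v])
        if v != last:
            rest.remove(terminal[v])
        rng.shuffle(rest)
        shuffled_edges[v] = rest + ([terminal[v]] if v != last else [])
    out = [seq[0]]
    cur = seq[0]
    counters = {v: 0 for v in vertices}
    for _ in range(len(seq) - 1):
        nxt = shuffled_edges[cur][counters[cur]]
        counters[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def discover_motif(seqs: Sequence[str], wmin: int = 15, wmax: int = 30,
                   mode: str = "zoops", seed: int = 0, site_prior: float = 0.8,
                   seed_stride: int = 1, n_refine: int = 3, n_calib: int = 8,
                   max_iter: int = 200, tol: float = 1e-6) -> MotifModel:
    """Discover the best shared ungapped motif over widths wmin..wmax.

    Both strands are searched; the width is chosen by a z-score of the
    observed LLR against *n_calib* dinucleotide-shuffled datasets per width
    (set ``n_calib=0`` to pick the raw best-LLR width when ``wmin == wmax``).
    Deterministic given *seed*.
    """
    if mode not in ("zoops", "oops"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(seqs) < 3:
        raise ValueError("need at least 3 sequences")
    if not 15 <= wmin <= wmax <= 30:
        raise ValueError("widths must satisfy 15 <= wmin <= wmax <= 30")
    short = [i for i, s in enumerate(seqs) if len(s) < wmax]
    if short:
        raise ValueError(f"sequences shorter than wmax={wmax}: indices {short}")
    prior = 1.0 if mode == "oops" else site_prior
    enc = _encode(seqs)
    bg = _background(enc)
    rng = np.random.default_rng(seed)
    best = None
    for w in range(wmin, wmax + 1):
        cand = _best_model_for_width(enc, w, bg, prior, seed_stride, n_refine,
                                     max_iter, tol)
        _, pwm, llr, hist, sites = cand
        if wmin == wmax or n_calib == 0:
            crit = llr
        else:
            null = []
            for _ in range(n_calib):
                shuf = _encode([dinucleotide_shuffle(s, rng) for s in seqs])
                nb = _best_model_for_width(shuf, w, _background(shuf), prior,
                                           max(seed_stride, 5), 1, 25, 1e-4)
                null.append(nb[2])
            mu, sd = float(np.mean(null)), float(np.std(null) + 1e-9)
            crit = (llr - mu) / sd
        if best is None or crit > best[0]:
            best = (crit, w, pwm, llr, hist, sites)
    _, w, pwm, llr, hist, sites = best
    kept = [(si, off, strand) for si, off, strand, post in sites if post > 0.5]
    return MotifModel(pwm=pwm, width=w, sites=kept, llr=llr, background=bg,
                      objective_history=hist)


def palindromicity(model: MotifModel | np.ndarray) -> float:
    """1 - mean total-variation distance between the PWM and its reverse
    complement; a perfect inverted repeat scores 1."""
    pwm = model.pwm if isinstance(model, MotifModel) else np.asarray(model)
    rc = pwm[::-1][:, _COMP_PERM]
    tv = 0.5 * np.abs(pwm - rc).sum(axis=1)  # per-column, in [0, 1]
    return float(1.0 - tv.mean())


def palindromize(pwm: np.ndarray) -> np.ndarray:
    """Average a PWM with its reverse complement (a perfect palindrome)."""
    rc = pwm[::-1][:, _COMP_PERM]
    return 0.5 * (pwm + rc)


def motif_significance(model: MotifModel, seqs: Sequence[str],
                       n_shuffles: int = 200, seed: int = 0,
                       site_prior: float = 0.8) -> float:
    """Empirical p-value of the fitted motif from a dinucleotide-shuffle null.

    significance = (1 + #{shuffled datasets with best same-width LLR >=
    observed}) / (1 + n_shuffles). The floor is 1/(n_shuffles + 1).
    """
    if n_shuffles <= 0:
        raise ValueError("n_shuffles must be positive")
    if n_shuffles < 20:
        warnings.warn("n_shuffles < 20: p-value resolution is coarse", stacklevel=2)
    rng = np.random.default_rng(seed)
    w = model.width
    exceed = 0
    for _ in range(n_shuffles):
        shuf = [dinucleotide_shuffle(s, rng) for s in seqs]
        enc = _encode(shuf)
        cand = _best_model_for_width(enc, w, _background(enc), site_prior,
                                     stride=5, n_refine=1, max_iter=25, tol=1e-4)
        if cand[2] >= model.llr:
            exceed += 1
    return (1 + exceed) / (1 + n_shuffles)


def sites_to_tsv(model: MotifModel, ids: Sequence[str], path) -> None:
    import pandas as pd

    rows = [{"sequence": ids[si], "offset": off, "strand": strand}
            for si, off, strand in model.sites]
    pd.DataFrame(rows, columns=["sequence", "offset", "strand"]).to_csv(
        path, sep="\t", index=False)
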