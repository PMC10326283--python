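"""Cross-validated decoding experiments, chance levels, and statistics.

Evaluation follows the study design for offline speech decoding: sentences
are split into 10 folds; all preprocessing state (z-score, PCA) is fitted on
the 9 training folds only; per held-out sentence and feature a Pearson
correlation and MSE are recorded.  Chance levels rerun the identical
pipeline after permuting neural feature frames across the whole corpus.
Real-vs-chance contrasts use a Bonferroni-corrected Wilcoxon signed-rank
test; multi-condition contrasts use the Quade rank test for complete block
designs with Conover pairwise post-hoc comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import art2ac
from .lindec import LinearDecoder
from .neurofeat import WindowingConfig
from .tracks import FeatureTrack, SentenceRecord


# ---------------------------------------------------------------------------
# metrics

def pearson_per_sentence(pred: FeatureTrack, truth: FeatureTrack):
    """Per-feature Pearson r over one whole sentence.

    Zero variance in either column makes r undefined; such features are
    reported as r = 0 with a degenerate flag.
    """
    if pred.n_frames != truth.n_frames:
        raise ValueError("prediction and truth frame counts differ")
    p = pred.data - pred.data.mean(axis=0)
    t = truth.data - truth.data.mean(axis=0)
    sp = np.sqrt((p**2).sum(axis=0))
    st = np.sqrt((t**2).sum(axis=0))
    degenerate = (sp < 1e-12) | (st < 1e-12)
    denom = np.where(degenerate, 1.0, sp * st)
    r = (p * t).sum(axis=0) / denom
    r = np.where(degenerate, 0.0, np.clip(r, -1.0, 1.0))
    return r, degenerate


def mse_per_sentence(pred: FeatureTrack, truth: FeatureTrack) -> np.ndarray:
    if pred.n_frames != truth.n_frames:
        raise ValueError("prediction and truth frame counts differ")
    return np.mean((pred.data - truth.data) ** 2, axis=0)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank with Bonferroni correction

@dataclass
class StatResult:
    name: str
    statistic: float
    df: tuple | float | None
    p_value: float
    p_corrected: float | None = None
    bonferroni_m: int | None = None
    pairwise: pd.DataFrame | None = None
    degenerate: bool = False


def _wilcoxon_exact_p(ranks2: np.ndarray, w2: float) -> float:
    """Exact two-sided p via the sign-enumeration distribution of W+.

    ``ranks2`` are doubled ranks (integers even with midranks); the
    distribution is built by dynamic programming over sign assignments.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2.astype(int):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(w2))
    p_low = counts[: w2 + 1].sum()
    p_high = counts[w2:].sum()
    return min(1.0, 2.0 * min(p_low, p_high))


def wilcoxon_bonferroni(
    real: np.ndarray, chance: np.ndarray, m: int = 1, exact_limit: int = 25
) -> StatResult:
    """Two-sided paired signed-rank test, Bonferroni-corrected by factor m.

    Exact enumeration for up to ``exact_limit`` nonzero pairs, normal
    approximation (with tie correction) beyond.  All-zero differences give
    p = 1 with a degenerate flag.
    """
    real = np.asarray(real, dtype=float)
    chance = np.asarray(chance, dtype=float)
    if real.shape != chance.shape:
        raise ValueError("paired samples must have equal length")
    d = real - chance
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return StatResult("wilcoxon", 0.0, None, 1.0, 1.0, m, degenerate=True)
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_limit:
        p = _wilcoxon_exact_p(np.round(2 * ranks), 2 * w_plus)
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(np.abs(d), return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts).sum()) / 48.0)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        z = (w_plus - mean) / np.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
    return StatResult("wilcoxon", w_plus, n, min(1.0, p),
                      min(1.0, m * p), m)


# ---------------------------------------------------------------------------
# Quade test with Conover post-hoc

def _quade_s_matrix(data: np.ndarray):
    """Quade weighted within-block rank scores S_ij for an n x k block design."""
    n, k = data.shape
    r = stats.rankdata(data, axis=1)
    ranges = data.max(axis=1) - data.min(axis=1)
    q = stats.rankdata(ranges)
    return q[:, None] * (r - (k + 1) / 2.0)


def quade_statistic(data: np.ndarray) -> tuple[float, float, float]:
    """(F, A, B) of the Quade test for one n x k block design."""
    n, k = data.shape
    s = _quade_s_matrix(data)
    sj = s.sum(axis=0)
    a = float((s**2).sum())
    b = float((sj**2).sum() / n)
    if a <= b + 1e-12:
        return np.inf, a, b
    return (n - 1) * b / (a - b), a, b


def quade_conover(
    data: np.ndarray | pd.DataFrame, alpha: float = 0.05
) -> StatResult:
    """Quade rank test over blocks (rows) x treatments (columns), with
    Conover pairwise comparisons when the omnibus test is significant.

    Blocks are weighted by the rank of their within-block range, so blocks
    where conditions differ most carry most weight.  All-identical
    treatments give p = 1 (guarded against the 0/0 statistic).
    """
    if isinstance(data, pd.DataFrame):
        cols = list(data.columns)
        arr = data.to_numpy(dtype=float)
    else:
        arr = np.asarray(data, dtype=float)
        cols = [f"t{j}" for j in range(arr.shape[1])]
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need an n x k complete block design with n,k >= 2")
    if not np.all(np.isfinite(arr)):
        raise ValueError("incomplete blocks: non-finite values present")
    n, k = arr.shape
    df1, df2 = k - 1, (n - 1) * (k - 1)

    if np.allclose(arr, arr[:, :1]):
        return StatResult("quade", 0.0, (df1, df2), 1.0, degenerate=True)

    f, a, b = quade_statistic(arr)
    if not np.isfinite(f):
        # perfect agreement of all block rankings: reject at machine level
        p = 0.0
    else:
        p = float(stats.f.sf(f, df1, df2))

    pairwise = None
    if p < alpha:
        s = _quade_s_matrix(arr)
        sj = s.sum(axis=0)
        denom = np.sqrt(max(2.0 * n * (a - b) / df2, 1e-300))
        tmat = np.abs(sj[:, None] - sj[None, :]) / denom
        pmat = 2.0 * stats.t.sf(tmat, df2)
        np.fill_diagonal(pmat, 1.0)
        pairwise = pd.DataFrame(pmat, index=cols, columns=cols)
    return StatResult("quade", f, (df1, df2), p, pairwise=pairwise)


def quade_statistic_batch(data: np.ndarray) -> np.ndarray:
    """Vectorized Quade F over a batch of block designs (m x n x k).

    Used for permutation oracles and type-I-error simulations.
    """
    m, n, k = data.shape
    r = stats.rankdata(data, axis=2)
    ranges = data.max(axis=2) - data.min(axis=2)
    q = stats.rankdata(ranges, axis=1)
    s = q[:, :, None] * (r - (k + 1) / 2.0)
    sj = s.sum(axis=1)
    a = (s**2).sum(axis=(1, 2))
    b = (sj**2).sum(axis=1) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (n - 1) * b / (a - b)
    f[a <= b + 1e-12] = np.inf
    return f


def quade_permutation_p(
    data: np.ndarray, n_permutations: int = 100_000, seed: int = 0
) -> float:
    """Permutation reference for the Quade test: treatment labels shuffled
    independently within each block; p = share of permuted F >= observed."""
    rng = np.random.default_rng(seed)
    f_obs, _, _ = quade_statistic(np.asarray(data, dtype=float))
    tiled = np.broadcast_to(data, (n_permutations, *data.shape)).copy()
    tiled = rng.permuted(tiled, axis=2)
    f_perm = quade_statistic_batch(tiled)
    return float((np.sum(f_perm >= f_obs) + 1) / (n_permutations + 1))


# ---------------------------------------------------------------------------
# cross-validated decoding experiments

PARADIGMS = ("direct", "indirect_finetune", "indirect_raw")


@dataclass
class ExperimentConfig:
    paradigm: str = "direct"
    decoder_kind: str = "pls"
    windowing: WindowingConfig = field(default_factory=lambda: WindowingConfig(210.0, 0.0))
    n_pca: int | None = None
    n_components: int = 12
    region: str = "all"
    n_folds: int = 10
    seed: int = 0
    finetune_seed: int = 0
    targets: tuple[str, ...] = ("mel", "f0")

    def __post_init__(self):
        if self.paradigm not in PARADIGMS:
            raise ValueError(f"unknown paradigm {self.paradigm!r}")


def assign_folds(sentences: list[SentenceRecord], n_folds: int, seed: int) -> np.ndarray:
    """Seeded fold assignment, stratified by condition so folds stay
    balanced; fold sizes differ by at most one."""
    if len(sentences) < n_folds:
        raise ValueError("fewer sentences than folds")
    rng = np.random.default_rng(seed)
    folds = np.empty(len(sentences), dtype=int)
    next_fold = 0
    for cond in sorted({s.condition for s in sentences}):
        idx = [i for i, s in enumerate(sentences) if s.condition == cond]
        rng.shuffle(idx)
        for i in idx:
            folds[i] = next_fold % n_folds
            next_fold += 1
    return folds


def _make_decoder(cfg: ExperimentConfig) -> LinearDecoder:
    return LinearDecoder(
        kind=cfg.decoder_kind,
        windowing=cfg.windowing,
        n_pca=cfg.n_pca,
        n_components=cfg.n_components,
        seed=cfg.seed,
    )


def _rows_for_sentence(sid, fold, pred, truth, condition, prefix=""):
    r, degen = pearson_per_sentence(pred, truth)
    mse = mse_per_sentence(pred, truth)
    rows = []
    for j, lab in enumerate(truth.labels):
        rows.append(dict(sentence_id=sid, fold=fold, feature=prefix + lab,
                         metric="pearson", value=float(r[j]),
                         condition=condition, degenerate=bool(degen[j])))
        rows.append(dict(sentence_id=sid, fold=fold, feature=prefix + lab,
                         metric="mse", value=float(mse[j]),
                         condition=condition, degenerate=bool(degen[j])))
    return rows


def crossval_run(
    sentences: list[SentenceRecord],
    cfg: ExperimentConfig,
    synthnet: art2ac.SynthNet | None = None,
    condition: str = "real",
    neural_key: str = "neural",
) -> pd.DataFrame:
    """Sentence-level k-fold cross-validated decoding.

    Each sentence record must carry a ``neural`` feature track (already
    region-selected), plus ``mel`` and ``f0`` targets; indirect paradigms
    additionally need an ``ema`` target and a pretrained synthesizer, and
    ``indirect_raw`` needs a ``mel_ref_warped`` track (the reference
    speaker's mel aligned onto the patient's timing) as ground truth.

    Per fold, all preprocessing and decoder state is fitted on the training
    folds only.  F0 is always decoded directly.  Returns a long-form table
    with one Pearson and one MSE row per sentence x feature.
    """
    if cfg.paradigm.startswith("indirect") and synthnet is None:
        raise ValueError("indirect paradigms need a pretrained synthesizer")
    folds = assign_folds(sentences, cfg.n_folds, cfg.seed)
    X = [s.tracks[neural_key] for s in sentences]
    rows: list[dict] = []

    for f in range(cfg.n_folds):
        tr = [i for i in range(len(sentences)) if folds[i] != f]
        te = [i for i in range(len(sentences)) if folds[i] == f]
        if not te:
            continue

        # F0 is decoded directly under every paradigm
        if "f0" in cfg.targets:
            f0_dec = _make_decoder(cfg).fit(
                [X[i] for i in tr], [sentences[i].tracks["f0"] for i in tr]
            )
            for i in te:
                pred = f0_dec.predict(X[i])
                rows += _rows_for_sentence(
                    sentences[i].sentence_id, f, pred, sentences[i].tracks["f0"],
                    condition,
                )
        if "mel" not in cfg.targets and cfg.paradigm == "direct":
            continue

        if cfg.paradigm == "direct":
            mel_dec = _make_decoder(cfg).fit(
                [X[i] for i in tr], [sentences[i].tracks["mel"] for i in tr]
            )
            for i in te:
                pred = mel_dec.predict(X[i])
                rows += _rows_for_sentence(
                    sentences[i].sentence_id, f, pred, sentences[i].tracks["mel"],
                    condition,
                )
            continue

        # indirect: decode EMA on ALL sentences with the fold's decoder
        ema_dec = _make_decoder(cfg).fit(
            [X[i] for i in tr], [sentences[i].tracks["ema"] for i in tr]
        )
        decoded = [ema_dec.predict(x) for x in X]
        for i in te:
            rows += _rows_for_sentence(
                sentences[i].sentence_id, f, decoded[i], sentences[i].tracks["ema"],
                condition,
            )

        if cfg.paradigm == "indirect_finetune":
            net = art2ac.fine_tune(
                synthnet,
                [(decoded[i], sentences[i].tracks["mel"]) for i in tr],
                seed=cfg.finetune_seed,
            )
            truth_key = "mel"
        else:  # indirect_raw: pretrained net, DTW-aligned reference truth
            net = synthnet
            truth_key = "mel_ref_warped"
        for i in te:
            if truth_key not in sentences[i].tracks:
                raise ValueError(f"sentence lacks a {truth_key!r} track")
            pred = art2ac.predict_mel(net, decoded[i])
            rows += _rows_for_sentence(
                sentences[i].sentence_id, f, pred, sentences[i].tracks[truth_key],
                condition, prefix="mel:",
            )
    return pd.DataFrame(rows)


def prepare_indirect_corpus(
    ref_corpus: list[SentenceRecord],
    pat_corpus: list[SentenceRecord],
    use_true_ema: bool = False,
) -> list[SentenceRecord]:
    """Attach the articulatory decoding targets and the warped-reference
    truth needed by the indirect paradigms.

    For each sentence pair this estimates the patient's articulatory
    trajectories by DTW transfer from the reference speaker (the study's
    Figure-1 pipeline) and stores them as the ``ema`` target, and warps the
    reference speaker's mel cepstrum onto the patient's timing as
    ``mel_ref_warped`` (the ground truth used when evaluating the
    non-fine-tuned synthesizer).  ``use_true_ema=True`` keeps the
    generator's true patient EMA instead of the DTW estimate (an oracle
    variant available only on synthetic data).
    """
    from . import artalign

    by_id = {s.sentence_id: s for s in ref_corpus}
    if set(by_id) != {s.sentence_id for s in pat_corpus}:
        raise ValueError("reference and patient corpora hold different sentences")
    out = []
    for pat in pat_corpus:
        ref = by_id[pat.sentence_id]
        est, path = artalign.estimate_patient_ema(ref, pat)
        m = est.n_frames
        ref_mel_rs = artalign.resample_to_length(ref.tracks["mel"], m)
        warped_mel = artalign.warp_reference_track(path, ref_mel_rs, m)
        tracks = {"mel_ref_warped": warped_mel}
        if not use_true_ema:
            tracks["ema"] = est
        out.append(pat.with_tracks(**tracks))
    return out


def shuffle_neural_frames(
    sentences: list[SentenceRecord], seed: int, neural_key: str = "neural"
) -> list[SentenceRecord]:
    """Permute neural feature frames uniformly across the whole corpus,
    leaving targets untouched (the chance-level manipulation)."""
    rng = np.random.default_rng(seed)
    stacked = np.vstack([s.tracks[neural_key].data for s in sentences])
    perm = rng.permutation(stacked.shape[0])
    stacked = stacked[perm]
    out = []
    start = 0
    for s in sentences:
        n = s.tracks[neural_key].n_frames
        track = FeatureTrack(stacked[start : start + n],
                             list(s.tracks[neural_key].labels))
        out.append(s.with_tracks(**{neural_key: track}))
        start += n
    return out


def chance_levels(
    sentences: list[SentenceRecord],
    cfg: ExperimentConfig,
    synthnet: art2ac.SynthNet | None = None,
    shuffle_seed: int = 0,
) -> pd.DataFrame:
    """Run the complete decoding pipeline on frame-shuffled neural data."""
    shuffled = shuffle_neural_frames(sentences, shuffle_seed)
    return crossval_run(shuffled, cfg, synthnet=synthnet, condition="chance")


def median_r(table: pd.DataFrame, feature_prefix: str = "", condition: str = "real") -> float:
    """Median per-sentence Pearson r over all features with a given prefix."""
    sel = table[(table.metric == "pearson") & (table.condition == condition)]
    if feature_prefix:
        sel = sel[sel.feature.str.startswith(feature_prefix)]
    return float(sel.value.median())


def sweep(
    sentences: list[SentenceRecord],
    base_cfg: ExperimentConfig,
    param: str,
    values: list,
    synthnet: art2ac.SynthNet | None = None,
) -> pd.DataFrame:
    """Re-run the cross-validated experiment for each value of one parameter
    (e.g. ``n_pca``, ``n_components``, or windowing fields given as
    ``context_ms`` / ``delay_ms``); returns the concatenated EvalTable with
    a ``sweep_value`` column."""
    tables = []
    for v in values:
        if param in ("context_ms", "delay_ms"):
            w = replace(base_cfg.windowing, **{param: v})
            cfg = replace(base_cfg, windowing=w)
        else:
            cfg = replace(base_cfg, **{param: v})
        t = crossval_run(sentences, cfg, synthnet=synthnet)
        t["sweep_param"] = param
        t["sweep_value"] = v
        tables.append(t)
    return pd.concat(tables, ignore_index=True)
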