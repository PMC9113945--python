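"""Semi-supervised classification of promoter CpG profiles.

``ProfileGRUClassifier`` distinguishes housekeeping-like (class 0) from
tissue-specific-like (class 1) genes from their 400-window TSS-centred CpG
density vectors. The profile is consumed as a length-400 sequence of scalar
tokens by a bidirectional GRU (1 layer, 16 hidden units per direction) whose
final states feed a 16→2 dense head with softmax. Training combines a
supervised binary cross-entropy term on labelled genes with an unsupervised
consistency term — the KL divergence between predictions on an unlabelled
gene and on an augmented copy of it (the "unsupervised data augmentation"
scheme) — so the large unlabelled gene set shapes the decision function.

The class-1 probability of a scored gene is its *CG likelihood*: low for
housekeeping-like sharp, high CpG peaks, high for flat, CpG-poor promoters.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .nn import Adam, BiGRUNet, cross_entropy, kl_divergence

__all__ = ["ProfileGRUClassifier", "augment_profile", "uda_loss", "evaluate_auc"]

# binary cross-entropy of an uninformative predictor; early stopping and
# best-weight restoration engage only below this chance plateau
_CHANCE_BCE = float(np.log(2.0))


def augment_profile(
    vectors: np.ndarray,
    rng: np.random.Generator,
    shift_max: int = 5,
    noise_sd: float = 0.1,
    window_sd: np.ndarray | None = None,
) -> np.ndarray:
    """Randomly perturb count profiles: circular shift plus truncated jitter.

    Each row is circularly shifted by a uniform integer in [−shift_max,
    shift_max], then perturbed by zero-mean Gaussian noise with per-window
    standard deviation ``noise_sd * window_sd`` (``window_sd`` defaults to the
    per-window std of ``vectors``), truncated at 0 so counts stay nonnegative.
    """
    V = np.atleast_2d(np.asarray(vectors, dtype=float))
    n, T = V.shape
    if shift_max >= T:
        raise ValueError("shift_max must be < profile length")
    out = np.empty_like(V)
    if shift_max > 0:
        shifts = rng.integers(-shift_max, shift_max + 1, size=n)
        for i in range(n):
            out[i] = np.roll(V[i], shifts[i])
    else:
        out[:] = V
    if noise_sd > 0:
        sd = window_sd if window_sd is not None else V.std(axis=0)
        out = out + rng.standard_normal(out.shape) * (noise_sd * sd)
        np.maximum(out, 0.0, out=out)
    return out if np.asarray(vectors).ndim == 2 else out[0]


def uda_loss(
    probs_labeled: np.ndarray,
    targets: np.ndarray,
    probs_unlabeled: np.ndarray | None,
    probs_augmented: np.ndarray | None,
    uda_weight: float,
) -> float:
    """Supervised BCE plus weighted consistency KL between unlabelled pairs.

    loss = BCE(labelled) + λ · mean KL(p(original) ‖ p(augmented)); with
    λ = 0 (or no unlabelled batch) this is plain supervised training.
    """
    loss = cross_entropy(probs_labeled, targets)
    if uda_weight > 0 and probs_unlabeled is not None:
        loss += uda_weight * kl_divergence(probs_unlabeled, probs_augmented)
    return loss


def evaluate_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC: P(score of a random class-1 gene > class-0), ties ½."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n1 = int(np.sum(labels == 1))
    n0 = int(np.sum(labels == 0))
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n0 * n1))


class ProfileGRUClassifier(BaseEstimator, ClassifierMixin):
    """Semi-supervised bidirectional-GRU classifier for windowed CpG profiles.

    Follows the sklearn semi-supervised convention: pass ``y`` with labels in
    {0, 1} and ``-1`` for unlabelled rows, which enter training only through
    the consistency term.

    Parameters
    ----------
    hidden_size : GRU hidden units per direction.
    fc_size : width of the dense layer between the GRU states and the logits.
    uda_weight : weight λ of the unsupervised consistency term; 0 disables it
        and reproduces a purely supervised run bit for bit.
    shift_max, noise_sd : augmentation magnitudes (windows; fraction of the
        per-window training std).
    epochs, batch_size, learning_rate : Adam training schedule.
    validation_fraction, patience : early stopping on held-out labelled BCE,
        armed only once validation BCE falls below the ln 2 chance plateau;
        the best-validation weights are then restored after training.
    random_state : seeds initialization, splitting, batching and augmentation.

    Attributes
    ----------
    classes_ : array([0, 1])
    mean_, scale_ : per-window standardization from the labelled training rows.
    net_ : the fitted numpy network.
    history_ : DataFrame with per-epoch supervised / consistency / validation loss.
    """

    def __init__(
        self,
        hidden_size: int = 16,
        fc_size: int = 16,
        uda_weight: float = 1.0,
        shift_max: int = 5,
        noise_sd: float = 0.1,
        epochs: int = 20,
        batch_size: int = 256,
        learning_rate: float = 3e-3,
        validation_fraction: float = 0.1,
        patience: int = 10,
        random_state: int = 0,
    ):
        self.hidden_size = hidden_size
        self.fc_size = fc_size
        self.uda_weight = uda_weight
        self.shift_max = shift_max
        self.noise_sd = noise_sd
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.validation_fraction = validation_fraction
        self.patience = patience
        self.random_state = random_state

    # -- helpers --------------------------------------------------------------

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean_) / self.scale_

    @staticmethod
    def _as_array(X) -> np.ndarray:
        X = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (genes × windows)")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains NaN or infinite values")
        return X

    def fit(self, X, y):
        X = self._as_array(X)
        y = np.asarray(y)
        labeled = y >= 0
        yl = y[labeled].astype(int)
        if not np.all(np.isin(y, (-1, 0, 1))):
            raise ValueError("labels must be 0, 1, or -1 for unlabelled")
        if len(np.unique(yl)) < 2:
            raise ValueError("training set must contain both classes")
        Xl_raw, Xu_raw = X[labeled], X[~labeled]
        self.classes_ = np.array([0, 1])

        ss = np.random.SeedSequence(self.random_state)
        s_init, s_split, s_batch, s_aug = ss.spawn(4)
        rng_split = np.random.default_rng(s_split)
        rng_batch = np.random.default_rng(s_batch)
        rng_aug = np.random.default_rng(s_aug)

        # stratified validation split from the labelled rows
        val_idx = []
        for cls in (0, 1):
            idx = np.flatnonzero(yl == cls)
            idx = rng_split.permutation(idx)
            n_val = max(1, int(round(self.validation_fraction * len(idx))))
            val_idx.append(idx[:n_val])
        val_idx = np.concatenate(val_idx)
        tr_mask = np.ones(len(yl), dtype=bool)
        tr_mask[val_idx] = False

        self.mean_ = Xl_raw[tr_mask].mean(axis=0)
        self.scale_ = np.maximum(Xl_raw[tr_mask].std(axis=0), 1e-8)
        self.window_sd_ = Xl_raw[tr_mask].std(axis=0)

        Xtr = self._standardize(Xl_raw[tr_mask])
        ytr = yl[tr_mask]
        Xval = self._standardize(Xl_raw[val_idx])
        yval = yl[val_idx]

        net = BiGRUNet(self.hidden_size, self.fc_size, rng=np.random.default_rng(s_init))
        opt = Adam(net.params, lr=self.learning_rate)
        use_uda = self.uda_weight > 0 and len(Xu_raw) > 0

        n_tr = len(Xtr)
        steps = max(int(np.ceil(n_tr / self.batch_size)), 8 if use_uda else 1)
        u_order = rng_batch.permutation(len(Xu_raw)) if use_uda else None
        u_pos = 0
        history = []
        best_val = np.inf
        best_params = net.copy_params()
        since_best = 0
        for epoch in range(self.epochs):
            order = rng_batch.permutation(n_tr)
            sup_sum = cons_sum = 0.0
            for step in range(steps):
                bi = order[(step * self.batch_size) % n_tr:][: self.batch_size]
                if len(bi) == 0:
                    bi = order[: self.batch_size]
                xb, yb = Xtr[bi], ytr[bi]
                grads = net.zero_grads()
                probs, cache = net.forward(xb, need_cache=True)
                onehot = np.zeros_like(probs)
                onehot[np.arange(len(yb)), yb] = 1.0
                net.backward((probs - onehot) / len(yb), cache, grads)
                sup_sum += cross_entropy(probs, yb)
                if use_uda:
                    take = min(self.batch_size, len(Xu_raw))
                    if u_pos + take > len(u_order):
                        u_order = rng_batch.permutation(len(Xu_raw))
                        u_pos = 0
                    ui = u_order[u_pos:u_pos + take]
                    u_pos += take
                    xu_raw = Xu_raw[ui]
                    q, _ = net.forward(self._standardize(xu_raw))
                    xa = self._standardize(
                        augment_profile(xu_raw, rng_aug, self.shift_max,
                                        self.noise_sd, window_sd=self.window_sd_)
                    )
                    pa, cache_a = net.forward(xa, need_cache=True)
                    # gradient of KL(stopgrad q ‖ p_aug) wrt augmented logits
                    net.backward(self.uda_weight * (pa - q) / len(ui), cache_a, grads)
                    cons_sum += kl_divergence(q, pa)
                opt.step(net.params, grads)
            val_probs = self._predict_in_batches(net, Xval)
            val_bce = cross_entropy(val_probs, yval)
            history.append(
                {"epoch": epoch, "supervised_loss": sup_sum / steps,
                 "consistency_loss": cons_sum / steps if use_uda else 0.0,
                 "validation_bce": val_bce}
            )
            if val_bce < best_val - 1e-6:
                best_val = val_bce
                best_params = net.copy_params()
                since_best = 0
            elif best_val < _CHANCE_BCE:
                # early stopping is armed only once validation loss has left
                # the chance-level plateau: this model class sits near ln 2
                # for several epochs before learning starts, and stopping (or
                # restoring "best" weights) inside that plateau would return
                # an untrained network
                since_best += 1
                if since_best >= self.patience:
                    break
        if best_val < _CHANCE_BCE:
            net.set_params_(best_params)
        self.net_ = net
        self.history_ = pd.DataFrame(history)
        self.n_features_in_ = X.shape[1]
        return self

    @staticmethod
    def _predict_in_batches(net: BiGRUNet, X: np.ndarray, batch: int = 256) -> np.ndarray:
        out = np.empty((len(X), 2))
        for i in range(0, len(X), batch):
            out[i:i + batch], _ = net.forward(X[i:i + batch])
        return out

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        X = self._as_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} windows, the model was fitted on {self.n_features_in_}"
            )
        return self._predict_in_batches(self.net_, self._standardize(X))

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def score_cg_likelihood(self, X) -> np.ndarray:
        """Per-gene CG likelihood: predicted probability of the tissue-specific class."""
        return self.predict_proba(X)[:, 1]

    def score(self, X, y) -> float:
        """Rank-based AUC of the CG likelihood against 0/1 labels."""
        return evaluate_auc(self.score_cg_likelihood(X), np.asarray(y))


def score_cg_likelihood(model: ProfileGRUClassifier, density: pd.DataFrame) -> pd.Series:
    """CG likelihood for every gene of a density matrix, order preserved."""
    return pd.Series(model.score_cg_likelihood(density), index=density.index, name="cg_likelihood")
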