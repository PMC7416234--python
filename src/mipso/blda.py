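"""Bayesian linear discriminant analysis via evidence maximisation.

The classifier is linear regression onto the +-1 class labels under a
zero-mean Gaussian prior on the weights (precision ``alpha``) and Gaussian
observation noise (precision ``beta``).  Both hyperparameters are set
automatically by fixed-point maximisation of the marginal likelihood
(the evidence framework), which is what gives the method its built-in
regularisation: no cross-validation of a ridge penalty is needed, so it
remains stable when the feature count exceeds the trial count.

The bias term is excluded from the prior.  Features are standardised and
centred internally, which decouples the bias (it becomes the mean target)
and lets the hyperparameter iterations run on the thin SVD of the centred
design: each update is O(r) for r = min(n, D) after a single decomposition.

Class decisions threshold the real-valued score at zero: a score >= 0 is
labelled +1, a score < 0 is labelled -1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["BayesianDiscriminant", "BayesianDiscriminantResults"]

_CLIP_LO, _CLIP_HI = 1e-12, 1e12


class BayesianDiscriminant:
    """Bayesian linear discriminant model.

    Parameters
    ----------
    endog : array-like, shape (n,)
        Targets.  Class labels in {-1, +1} for classification (both classes
        must appear at least twice); arbitrary finite reals are accepted for
        plain Bayesian linear regression.
    exog : array-like, shape (n, D)
        Feature matrix.
    standardize : bool, default True
        Z-score each feature from the training data before fitting.  Without
        it, wrapper selection over heterogeneous PSD magnitudes is biased
        toward high-power frequencies.
    target_coding : {"label", "balanced"}, default "label"
        "label" regresses onto the raw -1/+1 labels; "balanced" rescales the
        targets to +n/n_pos and -n/n_neg so unbalanced classes pull equally
        on the decision plane.
    """

    def __init__(
        self,
        endog,
        exog,
        *,
        standardize: bool = True,
        target_coding: str = "label",
    ) -> None:
        y = np.asarray(endog, dtype=np.float64).ravel()
        X = np.asarray(exog, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("exog must be 2-D (n_samples, n_features)")
        if len(y) != X.shape[0]:
            raise ValueError("endog and exog disagree on the number of samples")
        if X.shape[1] < 1:
            raise ValueError("at least one feature must be selected")
        if not np.all(np.isfinite(y)) or not np.all(np.isfinite(X)):
            raise ValueError("endog and exog must be finite")
        if target_coding not in ("label", "balanced"):
            raise ValueError("target_coding must be 'label' or 'balanced'")

        self._is_classification = bool(np.all(np.isin(y, (-1.0, 1.0))))
        if self._is_classification:
            n_pos = int(np.sum(y > 0))
            n_neg = int(np.sum(y < 0))
            if n_pos < 2 or n_neg < 2:
                raise ValueError(
                    "training data must contain at least two trials of each class"
                )
            if target_coding == "balanced":
                n = len(y)
                y = np.where(y > 0, n / n_pos, -n / n_neg)
        self.endog = y
        self.exog = X
        self.standardize = standardize
        self.target_coding = target_coding

    def fit(
        self,
        alpha: float | None = None,
        beta: float | None = None,
        *,
        alpha0: float = 1.0,
        beta0: float | None = None,
        max_iter: int = 200,
        tol: float = 1e-6,
    ) -> "BayesianDiscriminantResults":
        """Fit by fixed-point evidence maximisation.

        Passing ``alpha`` and/or ``beta`` pins that hyperparameter instead of
        updating it (both pinned reduces the fit to ridge regression with
        penalty ``alpha/beta``).
        """
        X, y = self.exog, self.endog
        n, D = X.shape

        mu = X.mean(axis=0)
        if self.standardize:
            sd = X.std(axis=0)
            sd[sd == 0] = 1.0
        else:
            sd = np.ones(D)
        Xs = (X - mu) / sd  # centred either way, so the bias decouples

        ybar = float(y.mean())
        yc = y - ybar
        yty = float(yc @ yc)

        U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
        keep = s > max(s.max(initial=0.0) * 1e-12, 1e-300)
        U, s, Vt = U[:, keep], s[keep], Vt[keep]
        s2 = s**2
        u = U.T @ yc

        a = float(alpha) if alpha is not None else float(alpha0)
        if beta is not None:
            b = float(beta)
        elif beta0 is not None:
            b = float(beta0)
        else:
            b = n / yty if yty > 0 else 1.0
        update_a, update_b = alpha is None, beta is None

        n_iter = 0
        converged = not (update_a or update_b)
        for n_iter in range(1, max_iter + 1):
            d = b * s2 / (b * s2 + a)
            gamma = float(d.sum())
            coef = (b * s / (b * s2 + a)) * u  # weights in the right-singular basis
            mnorm2 = float(coef @ coef)
            sse = max(yty - float(((2.0 * d - d**2) * u**2).sum()), 1e-300)
            a_new = a
            b_new = b
            if update_a:
                a_new = np.clip(gamma / max(mnorm2, 1e-300), _CLIP_LO, _CLIP_HI)
            if update_b:
                # one effective dof goes to the unpenalised bias
                b_new = np.clip(max(n - 1.0 - gamma, 1e-6) / sse, _CLIP_LO, _CLIP_HI)
            rel = max(abs(a_new - a) / max(a, 1e-300), abs(b_new - b) / max(b, 1e-300))
            a, b = float(a_new), float(b_new)
            if rel < tol:
                converged = True
                break

        coef = (b * s / (b * s2 + a)) * u
        weights = Vt.T @ coef  # weights in standardised feature space
        bias = ybar  # Xs is centred, so the bias is the target mean

        return BayesianDiscriminantResults(
            model=self,
            weights=weights,
            bias=float(bias),
            feature_mean=mu,
            feature_scale=sd,
            alpha=a,
            beta=b,
            n_iter=n_iter,
            converged=converged,
        )


@dataclass
class BayesianDiscriminantResults:
    """Fitted discriminant: weights, hyperparameters and prediction."""

    model: BayesianDiscriminant | None
    weights: np.ndarray
    bias: float
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    alpha: float
    beta: float
    n_iter: int
    converged: bool = True
    mask: np.ndarray | None = field(default=None)

    @property
    def params(self) -> np.ndarray:
        """Weight vector with the bias appended as the last entry."""
        return np.append(self.weights, self.bias)

    def predict(self, exog) -> np.ndarray:
        """Real-valued discriminant scores w'[x;1] after standardisation."""
        X = np.atleast_2d(np.asarray(exog, dtype=np.float64))
        if X.shape[1] != len(self.weights):
            raise ValueError(
                f"expected {len(self.weights)} features, got {X.shape[1]}; "
                "apply the same selection mask used for training"
            )
        return ((X - self.feature_mean) / self.feature_scale) @ self.weights + self.bias

    def classify(self, exog) -> np.ndarray:
        """Hard labels: score >= 0 maps to +1, score < 0 to -1."""
        return np.where(self.predict(exog) >= 0, 1, -1).astype(np.int64)

    def summary(self) -> str:
        lines = [
            "Bayesian Linear Discriminant Results",
            "=" * 40,
            f"n features          {len(self.weights)}",
            f"alpha (prior prec.) {self.alpha:.6g}",
            f"beta (noise prec.)  {self.beta:.6g}",
            f"iterations          {self.n_iter}"
            + ("" if self.converged else "  (not converged)"),
            f"||weights||_2       {np.linalg.norm(self.weights):.6g}",
            f"bias                {self.bias:.6g}",
        ]
        return "\n".join(lines)

    def to_json(self) -> str:
        payload = {
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "feature_mean": self.feature_mean.tolist(),
            "feature_scale": self.feature_scale.tolist(),
            "alpha": self.alpha,
            "beta": self.beta,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "mask": None if self.mask is None else np.asarray(self.mask).astype(int).tolist(),
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "BayesianDiscriminantResults":
        d = json.loads(text)
        return cls(
            model=None,
            weights=np.asarray(d["weights"], dtype=np.float64),
            bias=float(d["bias"]),
            feature_mean=np.asarray(d["feature_mean"], dtype=np.float64),
            feature_scale=np.asarray(d["feature_scale"], dtype=np.float64),
            alpha=float(d["alpha"]),
            beta=float(d["beta"]),
            n_iter=int(d["n_iter"]),
            converged=bool(d["converged"]),
            mask=None if d.get("mask") is None else np.asarray(d["mask"], dtype=np.uint8),
        )
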