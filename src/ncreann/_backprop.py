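"""Incremental error back-propagation kernel (numba-compiled).

Single hidden layer, tanh hidden units, linear outputs.  Weights are
updated per pattern ("incremental" mode) with momentum; the learning
rate adapts per epoch: grown when the epoch training error decreases,
shrunk — with the epoch's updates rejected — when it grows by more
than a set fraction.  Early stopping monitors a validation partition
and the best-validation weights are returned.
"""

import numpy as np
from numba import njit

__all__ = ["train_incremental", "dataset_mse", "forward"]


@njit(cache=True)
def _mse(X, Y, idx, W1, b1, W2, b2):
    H = W1.shape[0]
    M = W2.shape[0]
    acc = 0.0
    h = np.empty(H)
    for r in idx:
        x = X[r]
        s = 0.0
        for j in range(H):
            u = b1[j]
            for k in range(x.shape[0]):
                u += W1[j, k] * x[k]
            h[j] = np.tanh(u)
        for i in range(M):
            yi = b2[i]
            for j in range(H):
                yi += W2[i, j] * h[j]
            d = yi - Y[r, i]
            s += d * d
        acc += s
    return acc / (len(idx) * M) if len(idx) > 0 else 0.0


@njit(cache=True)
def dataset_mse(X, Y, idx, W1, b1, W2, b2):
    """Mean squared error over rows ``idx``, pooled over output nodes."""
    return _mse(X, Y, idx, W1, b1, W2, b2)


@njit(cache=True)
def forward(X, W1, b1, W2, b2):
    """Network predictions for a row-matrix of inputs."""
    n = X.shape[0]
    H = W1.shape[0]
    M = W2.shape[0]
    out = np.empty((n, M))
    h = np.empty(H)
    for r in range(n):
        for j in range(H):
            u = b1[j]
            for k in range(X.shape[1]):
                u += W1[j, k] * X[r, k]
            h[j] = np.tanh(u)
        for i in range(M):
            yi = b2[i]
            for j in range(H):
                yi += W2[i, j] * h[j]
            out[r, i] = yi
    return out


@njit(cache=True)
def train_incremental(X, Y, train_idx, val_idx,
                      W1, b1, W2, b2,
                      lr0, momentum, lr_inc, lr_dec, max_perf_inc,
                      max_epochs, patience, seed):
    """Train in place; returns best-validation weights and diagnostics.

    Returns (W1, b1, W2, b2, n_epochs, best_val_mse, aborted).
    ``aborted`` is 1 when the error diverged to non-finite values more
    than 5 times in a row despite halving the learning rate.
    """
    np.random.seed(seed)
    H, D = W1.shape
    M = W2.shape[0]
    vW1 = np.zeros_like(W1)
    vb1 = np.zeros_like(b1)
    vW2 = np.zeros_like(W2)
    vb2 = np.zeros_like(b2)
    lr = lr0
    n_train = len(train_idx)
    order = train_idx.copy()
    prev_mse = _mse(X, Y, train_idx, W1, b1, W2, b2)
    best_val = np.inf
    bW1, bb1, bW2, bb2 = W1.copy(), b1.copy(), W2.copy(), b2.copy()
    bad_checks = 0
    diverge_retries = 0
    aborted = 0
    h = np.empty(H)
    delta = np.empty(H)
    epoch = 0
    while epoch < max_epochs:
        epoch += 1
        # snapshot for possible rejection of this epoch's updates
        sW1, sb1, sW2, sb2 = W1.copy(), b1.copy(), W2.copy(), b2.copy()
        svW1, svb1, svW2, svb2 = vW1.copy(), vb1.copy(), vW2.copy(), vb2.copy()
        # Fisher-Yates shuffle of the presentation order
        for i in range(n_train - 1, 0, -1):
            j = np.random.randint(0, i + 1)
            tmp = order[i]
            order[i] = order[j]
            order[j] = tmp
        for r in order:
            x = X[r]
            for jj in range(H):
                u = b1[jj]
                for k in range(D):
                    u += W1[jj, k] * x[k]
                h[jj] = np.tanh(u)
            for jj in range(H):
                delta[jj] = 0.0
            for i in range(M):
                yi = b2[i]
                for jj in range(H):
                    yi += W2[i, jj] * h[jj]
                e = yi - Y[r, i]
                # output layer update
                for jj in range(H):
                    vW2[i, jj] = momentum * vW2[i, jj] - lr * e * h[jj]
                    delta[jj] += W2[i, jj] * e
                    W2[i, jj] += vW2[i, jj]
                vb2[i] = momentum * vb2[i] - lr * e
                b2[i] += vb2[i]
            for jj in range(H):
                dj = delta[jj] * (1.0 - h[jj] * h[jj])
                for k in range(D):
                    vW1[jj, k] = momentum * vW1[jj, k] - lr * dj * x[k]
                    W1[jj, k] += vW1[jj, k]
                vb1[jj] = momentum * vb1[jj] - lr * dj
                b1[jj] += vb1[jj]
        mse = _mse(X, Y, train_idx, W1, b1, W2, b2)
        if not np.isfinite(mse):
            # divergence: reject, halve the rate, retry the epoch
            W1[:], b1[:], W2[:], b2[:] = sW1, sb1, sW2, sb2
            vW1[:], vb1[:], vW2[:], vb2[:] = svW1, svb1, svW2, svb2
            lr *= 0.5
            diverge_retries += 1
            epoch -= 1
            if diverge_retries > 5:
                aborted = 1
                break
            continue
        diverge_retries = 0
        if mse > (1.0 + max_perf_inc) * prev_mse:
            # reject the epoch's updates, shrink the rate
            W1[:], b1[:], W2[:], b2[:] = sW1, sb1, sW2, sb2
            vW1[:] = 0.0
            vb1[:] = 0.0
            vW2[:] = 0.0
            vb2[:] = 0.0
            lr *= lr_dec
        else:
            if mse < prev_mse:
                lr *= lr_inc
            prev_mse = mse
        if lr < 1e-8:
            lr = 1e-8
        elif lr > 1.0:
            lr = 1.0
        if len(val_idx) > 0:
            vmse = _mse(X, Y, val_idx, W1, b1, W2, b2)
            if vmse < best_val:
                best_val = vmse
                bW1[:], bb1[:], bW2[:], bb2[:] = W1, b1, W2, b2
                bad_checks = 0
            else:
                bad_checks += 1
                if bad_checks >= patience:
                    break
        else:
            bW1[:], bb1[:], bW2[:], bb2[:] = W1, b1, W2, b2
            best_val = mse
    return bW1, bb1, bW2, bb2, epoch, best_val, aborted
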