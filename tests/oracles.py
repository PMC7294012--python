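"""Independent brute-force oracles shared across test modules."""

import numpy as np


def brute_force_maps(img, window=5, amads=0.6457, eps=1e-6):
    """Naive double-loop AMED/AMAD/mROR using pure-python sorting.

    Deliberately avoids numpy medians and the package's sliding windows so
    it stays an independent check of the vectorized implementations.
    """
    h, w = img.shape
    r = window // 2
    pad = np.pad(img, r, mode="symmetric")
    amed = np.empty((h, w))
    amad = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            y = sorted(pad[i : i + window, j : j + window].ravel().tolist())
            n = len(y)
            med = y[n // 2] if n % 2 else 0.5 * (y[n // 2 - 1] + y[n // 2])
            dev = sorted(abs(v - med) for v in y)
            mad = dev[n // 2] if n % 2 else 0.5 * (dev[n // 2 - 1] + dev[n // 2])
            amed[i, j], amad[i, j] = med, mad
    namad = amad / amads
    mror = np.abs(img - amed) / np.maximum(namad, eps)
    return amed, amad, mror
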