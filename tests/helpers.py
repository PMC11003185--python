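"""Test-only helpers: a synthetic FCS writer and independent metric oracles.

The FCS writer exists solely to create synthetic fixtures for the read-only
FCS parser; it is not part of the package surface. The oracles are brute-force
reference implementations kept deliberately independent of the code paths
they check.
"""

from __future__ import annotations

import itertools
from pathlib import Path

import numpy as np
from scipy.optimize import linprog


def write_fcs(path: Path, data: np.ndarray, channel_names: list[str]) -> Path:
    """Write a minimal synthetic FCS 3.0 file (list mode, float32, little
    endian) holding ``data`` (events x channels)."""
    data = np.asarray(data, dtype="<f4")
    n_tot, n_par = data.shape
    body = data.tobytes()
    header_len = 58
    d = "/"

    def text_segment(begin_data: int, end_data: int) -> bytes:
        kw = {
            "$BEGINANALYSIS": "0", "$ENDANALYSIS": "0",
            "$BEGINSTEXT": "0", "$ENDSTEXT": "0",
            "$BEGINDATA": f"{begin_data:010d}", "$ENDDATA": f"{end_data:010d}",
            "$BYTEORD": "1,2,3,4", "$DATATYPE": "F", "$MODE": "L",
            "$NEXTDATA": "0", "$PAR": str(n_par), "$TOT": str(n_tot),
        }
        for i, name in enumerate(channel_names, start=1):
            kw[f"$P{i}N"] = name
            kw[f"$P{i}B"] = "32"
            kw[f"$P{i}E"] = "0,0"
            kw[f"$P{i}R"] = "262144"
        return (d + d.join(f"{k}{d}{v}" for k, v in kw.items()) + d).encode()

    # fixed-width $BEGINDATA/$ENDDATA keep the TEXT length stable
    text = text_segment(0, 0)
    text_begin = header_len
    text_end = text_begin + len(text) - 1
    data_begin = text_end + 1
    data_end = data_begin + len(body) - 1
    text = text_segment(data_begin, data_end)
    header = (
        b"FCS3.0    "
        + f"{text_begin:8d}".encode()
        + f"{text_end:8d}".encode()
        + f"{data_begin:8d}".encode()
        + f"{data_end:8d}".encode()
        + f"{0:8d}".encode()
        + f"{0:8d}".encode()
    )
    assert len(header) == header_len
    path.write_bytes(header + text + body)
    return path


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------


def ari_pair_counting(labels1, labels2) -> float:
    """ARI by explicit enumeration of all cell pairs."""
    labels1, labels2 = list(labels1), list(labels2)
    n = len(labels1)
    s11 = s00 = s10 = s01 = 0
    for i, j in itertools.combinations(range(n), 2):
        same1 = labels1[i] == labels1[j]
        same2 = labels2[i] == labels2[j]
        if same1 and same2:
            s11 += 1
        elif same1:
            s10 += 1
        elif same2:
            s01 += 1
        else:
            s00 += 1
    total = s11 + s10 + s01 + s00
    a = s11 + s10  # same in 1
    b = s11 + s01  # same in 2
    expected = a * b / total
    max_index = (a + b) / 2
    if max_index == expected:
        return 1.0
    return (s11 - expected) / (max_index - expected)


def nmi_entropy(labels1, labels2) -> float:
    """NMI (arithmetic normalisation) from explicit entropy sums."""
    l1, l2 = np.asarray(labels1), np.asarray(labels2)
    n = len(l1)

    def entropy(labels):
        _, counts = np.unique(labels, return_counts=True)
        p = counts / n
        return -np.sum(p * np.log(p))

    h1, h2 = entropy(l1), entropy(l2)
    if h1 == 0 or h2 == 0:
        return 0.0
    mi = 0.0
    for u in np.unique(l1):
        for v in np.unique(l2):
            nij = np.sum((l1 == u) & (l2 == v))
            if nij > 0:
                pij = nij / n
                mi += pij * np.log(pij / ((np.sum(l1 == u) / n) * (np.sum(l2 == v) / n)))
    return mi / ((h1 + h2) / 2)


def emd_transport_lp(p: np.ndarray, q: np.ndarray, bin_width: float) -> float:
    """Optimal-transport cost between two binned mass vectors, solved as an LP
    with cost |i - j| * bin_width per unit mass."""
    p, q = np.asarray(p, float), np.asarray(q, float)
    p, q = p / p.sum(), q / q.sum()
    n = len(p)
    cost = np.abs(np.subtract.outer(np.arange(n), np.arange(n))) * bin_width
    # variables f_ij >= 0; rows sum to p, columns sum to q
    a_eq = []
    b_eq = []
    for i in range(n):
        row = np.zeros(n * n)
        row[i * n : (i + 1) * n] = 1
        a_eq.append(row)
        b_eq.append(p[i])
    for j in range(n):
        col = np.zeros(n * n)
        col[j::n] = 1
        a_eq.append(col)
        b_eq.append(q[j])
    res = linprog(cost.ravel(), A_eq=np.array(a_eq), b_eq=np.array(b_eq),
                  bounds=(0, None), method="highs")
    assert res.success
    return float(res.fun)


def best_modularity_bipartition(n: int, edges: list[tuple[int, int]]):
    """Exhaustive search over all 2-partitions maximising Newman modularity."""
    m = len(edges)
    deg = np.zeros(n)
    for a, b in edges:
        deg[a] += 1
        deg[b] += 1
    best_q, best_part = -np.inf, None
    for bits in range(1, 2 ** (n - 1)):  # node 0 fixed to side 0
        side = [(bits >> i) & 1 for i in range(n)]
        q = 0.0
        for c in (0, 1):
            members = [i for i in range(n) if side[i] == c]
            e_in = sum(1 for a, b in edges if side[a] == c and side[b] == c)
            d = sum(deg[i] for i in members)
            q += e_in / m - (d / (2 * m)) ** 2
        if q > best_q:
            best_q, best_part = q, side
    groups = [frozenset(i for i in range(n) if best_part[i] == c) for c in (0, 1)]
    return set(groups)
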