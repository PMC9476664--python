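"""Natural-blocking significance lists for screened tensor contractions.

A significance list maps each left index i to the sorted set {j : |A_ij| > ε}
of significant right indices (strict inequality; boundary ties excluded).
Lists are stored CSR-like (one sorted index array plus offsets), which makes
batched contractions deterministic.  Three screen builders are provided:
collocation magnitudes (grid–orbital pairs), pairwise collocation products
(orbital–orbital pairs), and the set composition through a shared middle
index (indirect exponential coupling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class NBConfig:
    """Thresholds for the three list families of the exchange screening."""

    eps_Sj: float = 1e-3   # grid – occupied-orbital pairs
    eps_bR: float = 1e-2   # grid – virtual-orbital pairs
    eps_bj: float = 1e-2   # virtual – occupied orbital pairs

    def __post_init__(self):
        if min(self.eps_Sj, self.eps_bR, self.eps_bj) < 0:
            raise ValueError("NB thresholds must be >= 0")

    def scaled(self, factor: float) -> "NBConfig":
        return NBConfig(self.eps_Sj * factor, self.eps_bR * factor,
                        self.eps_bj * factor)


@dataclass
class SignificanceList:
    n_left: int
    n_right: int
    indices: np.ndarray       # concatenated sorted members
    offsets: np.ndarray       # (n_left+1,)
    threshold: float = 0.0

    @property
    def n_pairs(self) -> int:
        return int(len(self.indices))

    def members(self, i: int) -> np.ndarray:
        return self.indices[self.offsets[i]: self.offsets[i + 1]]

    def to_bool(self) -> np.ndarray:
        M = np.zeros((self.n_left, self.n_right), bool)
        for i in range(self.n_left):
            M[i, self.members(i)] = True
        return M

    @classmethod
    def from_bool(cls, M: np.ndarray, threshold: float = 0.0):
        idx, off = [], [0]
        for i in range(M.shape[0]):
            j = np.nonzero(M[i])[0]
            idx.append(j)
            off.append(off[-1] + len(j))
        return cls(n_left=M.shape[0], n_right=M.shape[1],
                   indices=np.concatenate(idx) if idx else np.empty(0, int),
                   offsets=np.array(off), threshold=threshold)


def build_list(A: np.ndarray, eps: float) -> SignificanceList:
    """j ∈ j_i iff |A_ij| > ε (strict); ε = 0 keeps every pair."""
    A = np.asarray(A)
    if not np.all(np.isfinite(A)):
        raise ValueError("screening matrix must be finite")
    return SignificanceList.from_bool(np.abs(A) > eps, threshold=eps)


def transpose_list(L: SignificanceList) -> SignificanceList:
    return SignificanceList.from_bool(L.to_bool().T, threshold=L.threshold)


def compose_lists(L_mid_right: SignificanceList,
                  L_mid_left: SignificanceList) -> SignificanceList:
    """Indirect coupling: i -> {j : ∃ m with m ∈ mid(i) and j ∈ right(m)}.

    ``L_mid_left`` maps left indices to middle indices, ``L_mid_right`` maps
    middle indices to right indices (a boolean matrix product).
    """
    if L_mid_left.n_right != L_mid_right.n_left:
        raise ValueError("middle-index dimensions do not match")
    Bl = L_mid_left.to_bool()          # (n_left, n_mid)
    Br = L_mid_right.to_bool()         # (n_mid, n_right)
    return SignificanceList.from_bool(Bl @ Br)


def grid_orbital_screen(Xc: np.ndarray) -> np.ndarray:
    """Element-magnitude screen |X̲_iP| for grid–orbital pairs."""
    return np.abs(np.asarray(Xc))


def orbital_orbital_screen(X_occ: np.ndarray, X_virt: np.ndarray) -> np.ndarray:
    """max_P |X̲_iP X̅_aP| — orbital pairs with non-negligible co-density.

    Returns the screen with occupied index on the left, virtual on the right.
    """
    return np.max(np.abs(X_occ[:, None, :] * X_virt[None, :, :]), axis=2)
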