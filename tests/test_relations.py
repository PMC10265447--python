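"""Relation builders: fingerprints, similarities, incidence, affinity, negatives."""

import numpy as np
import pytest
from scipy import sparse as sp

from erfusion.relations import (AffinityRecord, FingerprintSet, incidence_matrix,
                                load_fingerprints, row_normalize, sample_negatives,
                                smiles_fingerprints, tanimoto_matrix,
                                transform_affinity, write_fingerprints)


def _random_fps(rng, n=50, n_bits=128, max_on=20):
    indptr = [0]
    indices = []
    for _ in range(n):
        k = int(rng.integers(0, max_on))
        indices.extend(sorted(rng.choice(n_bits, size=k, replace=False)))
        indptr.append(len(indices))
    bits = sp.csr_matrix((np.ones(len(indices), np.int8), indices, indptr),
                         shape=(n, n_bits))
    return FingerprintSet(ids=[f"D{i}" for i in range(n)], bits=bits, n_bits=n_bits)


def test_tanimoto_equals_per_pair_set_arithmetic(rng):
    fps = _random_fps(rng)
    S = tanimoto_matrix(fps)
    for i in range(len(fps.ids)):
        for j in range(len(fps.ids)):
            a, b = fps.onbits(i), fps.onbits(j)
            expected = len(a & b) / len(a | b) if (a | b) else 0.0
            assert S[i, j] == pytest.approx(expected, abs=1e-12)
    np.testing.assert_allclose(S, S.T)


def test_tanimoto_hand_cases():
    def fp(*onbits_rows):
        indptr = [0]
        idx = []
        for row in onbits_rows:
            idx.extend(row)
            indptr.append(len(idx))
        bits = sp.csr_matrix((np.ones(len(idx), np.int8), idx, indptr),
                             shape=(len(onbits_rows), 10))
        return FingerprintSet(ids=[f"x{i}" for i in range(len(onbits_rows))],
                              bits=bits, n_bits=10)

    S = tanimoto_matrix(fp([1, 2, 3], [2, 3, 4], [7, 8], []))
    assert S[0, 0] == 1.0                      # identical non-empty
    assert S[0, 1] == pytest.approx(2 / 4)     # {1,2,3} vs {2,3,4}
    assert S[0, 2] == 0.0                      # disjoint
    assert S[3, 3] == 0.0                      # both empty defined as 0


def test_row_normalize_arithmetic_idempotence_and_errors():
    M = np.array([[2.0, 2.0, 4.0], [0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
    N = row_normalize(M)
    np.testing.assert_allclose(N[0], [0.25, 0.25, 0.5])
    np.testing.assert_allclose(N[1], 0.0)              # zero row unchanged
    sums = N.sum(axis=1)
    assert all(s == pytest.approx(0.0) or s == pytest.approx(1.0) for s in sums)
    np.testing.assert_allclose(row_normalize(N), N)    # idempotent
    with pytest.raises(ValueError):
        row_normalize(np.array([[-1.0, 2.0]]))


def test_incidence_matrix_round_trip_and_counts():
    ann = {"P0": {"kinase", "SH2"}, "P1": {"kinase"}, "P2": {"kinase", "PDZ"}}
    id_index = {"P0": 0, "P1": 1, "P2": 2, "P3": 3}
    M, vocab = incidence_matrix(ann, id_index)
    assert vocab == sorted({"kinase", "SH2", "PDZ"})
    assert M.shape == (4, 3)
    assert M[0].sum() == 2
    assert M[:, vocab.index("kinase")].sum() == 3
    assert M[3].sum() == 0
    # round trip
    rebuilt = {pid: {vocab[j] for j in np.flatnonzero(M[i])}
               for pid, i in id_index.items() if M[i].any()}
    assert rebuilt == ann
    with pytest.raises(KeyError):
        incidence_matrix({"P9": {"x"}}, id_index)


def test_fingerprint_file_round_trip(tmp_path, rng):
    path = tmp_path / "fp.tsv"
    path.write_text("D1\t3,17,900\nD2\t\nD3\t0,1027\n")
    fps = load_fingerprints(path, n_bits=1028)
    assert fps.onbits(0) == {3, 17, 900}
    assert fps.onbits(1) == set()
    out = tmp_path / "fp2.tsv"
    write_fingerprints(fps, out)
    again = load_fingerprints(out, n_bits=1028)
    assert (fps.bits != again.bits).nnz == 0
    path.write_text("D1\t2000\n")
    with pytest.raises(ValueError):
        load_fingerprints(path, n_bits=1028)


def test_high_dimensional_fingerprints_are_sparse(rng):
    """30-60 on-bits in 30000 dimensions is 0.1-0.2% density."""
    indptr = [0]
    indices = []
    for _ in range(40):
        k = int(rng.integers(30, 61))
        indices.extend(sorted(rng.choice(30000, size=k, replace=False)))
        indptr.append(len(indices))
    bits = sp.csr_matrix((np.ones(len(indices), np.int8), indices, indptr),
                         shape=(40, 30000))
    fps = FingerprintSet(ids=[f"D{i}" for i in range(40)], bits=bits, n_bits=30000)
    assert 0.001 <= fps.density <= 0.002


def test_smiles_fingerprints_skip_unparsable():
    fps = smiles_fingerprints({"aspirin": "CC(=O)Oc1ccccc1C(=O)O",
                               "broken": "not_a_smiles",
                               "ethanol": "CCO"}, n_bits=1028)
    assert fps.ids == ["aspirin", "ethanol"]
    assert fps.bits.shape == (2, 1028)
    assert fps.onbits(0)  # aspirin has some substructure bits


def test_affinity_transform_anchors_and_monotonicity():
    vals = transform_affinity([AffinityRecord("d", "p", 1e9),
                               AffinityRecord("d", "p", 1.0),
                               AffinityRecord("d", "p", 100.0)])
    assert vals[0] == pytest.approx(0.0)
    assert vals[1] == pytest.approx(9.0)
    assert vals[2] == pytest.approx(7.0)
    assert vals[1] > vals[2] > vals[0]  # smaller Kd -> larger pKd
    with pytest.raises(ValueError):
        transform_affinity([0.0])


def test_negative_sampling_count_disjointness_determinism(rng):
    n_d, n_p = 100, 50
    pos = np.column_stack([rng.integers(0, n_d, 1923), rng.integers(0, n_p, 1923)])
    pos = np.unique(pos, axis=0)
    neg = sample_negatives(pos, n_d, n_p, ratio=1.0, seed=3)
    assert len(neg) == len(pos)
    pk = set(map(tuple, pos.tolist()))
    nk = set(map(tuple, neg.tolist()))
    assert not (pk & nk)
    assert len(nk) == len(neg)  # without replacement
    neg2 = sample_negatives(pos, n_d, n_p, ratio=1.0, seed=3)
    np.testing.assert_array_equal(neg, neg2)
    # exhaustion: fully positive matrix
    full = np.column_stack(np.divmod(np.arange(12), 4))
    with pytest.raises(ValueError):
        sample_negatives(full, 3, 4, ratio=1.0, seed=0)
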