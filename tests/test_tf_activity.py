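"""Motif parsing, dinucleotide shuffling, motif insertion and ISM."""

from collections import Counter
from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import probatac.model as M
from probatac.model import AccessibilityResults, ModelConfig
from probatac.synthetic import make_pwm
from probatac.tf_activity import (activity_library, dinucleotide_shuffle, ism,
                                  motif_activity, pwm_ism_score,
                                  read_jaspar_pfm)

JASPAR_TEXT = """\
>MA0001.1 TESTA
A  [ 10  0  0 10 ]
C  [  0 10  0  0 ]
G  [  0  0 10  0 ]
T  [  0  0  0  0 ]
>MA0002.1 TESTB
A  [ 5 5 5 5 ]
C  [ 5 5 5 5 ]
G  [ 5 5 5 5 ]
T  [ 5 5 5 5 ]
"""


def dinuc_counts(seq):
    return Counter(zip(seq[:-1], seq[1:]))


@pytest.fixture(scope="module")
def tiny_results():
    """Small random-weight model, adequate for plumbing/invariant checks."""
    cfg = ModelConfig(input_length=30, n_cells=5, d=8, n_heads=2, n_layers=2,
                      ffw_width=12, stem_kernel=5, enc_kernel=3, seq_channels=2,
                      seq_kernel=3, embedding_size=4, stem_threshold=100,
                      attention_mode="exact", seed=1)
    net = M._Network(cfg)
    return AccessibilityResults(None, net, {"train_loss": [], "val_loss": []},
                                -1, float("nan"))


# ---------------------------------------------------------------------------
# JASPAR parsing
# ---------------------------------------------------------------------------


def test_read_jaspar_counts_to_probabilities(tmp_path):
    p = tmp_path / "m.jaspar"
    p.write_text(JASPAR_TEXT)
    lib = read_jaspar_pfm(p)
    assert lib.names == ["TESTA", "TESTB"]
    a = lib.motifs[0]
    assert np.allclose(a.matrix[0], [1, 0, 0, 0])
    assert a.consensus == "ACGA"
    assert np.allclose(lib.motifs[1].matrix, 0.25)   # all-equal counts


def test_read_jaspar_malformed_record(tmp_path):
    p = tmp_path / "bad.jaspar"
    p.write_text(">MA0003.1 X\nA [ 1 2 ]\nC [ 1 2 ]\nG [ 1 2 ]\n")
    with pytest.raises(Exception):
        read_jaspar_pfm(p)


# ---------------------------------------------------------------------------
# dinucleotide shuffling
# ---------------------------------------------------------------------------


def test_shuffle_unique_arrangement_is_identity():
    assert dinucleotide_shuffle("AAAA", seed=0) == "AAAA"


def test_shuffle_too_short():
    with pytest.raises(ValueError):
        dinucleotide_shuffle("A", seed=0)


def test_shuffle_eight_mer_member_of_enumerated_valid_set():
    seq = "ACGTCAGT"
    ref = dinuc_counts(seq)
    valid = {p for p in ("".join(t) for t in set(permutations(seq)))
             if dinuc_counts(p) == ref and p[0] == seq[0] and p[-1] == seq[-1]}
    outs = {dinucleotide_shuffle(seq, seed=s) for s in range(20)}
    assert outs <= valid
    assert len(valid) > 1        # the 8-mer genuinely has alternatives


def test_shuffle_deterministic_per_seed():
    seq = "ACGGTACCGGTTAACG"
    assert dinucleotide_shuffle(seq, seed=5) == dinucleotide_shuffle(seq, seed=5)


@given(st.text(alphabet="ACGT", min_size=2, max_size=60))
@settings(max_examples=200, deadline=None)
def test_shuffle_preserves_dinucleotide_counts(seq):
    out = dinucleotide_shuffle(seq, seed=11)
    assert dinuc_counts(out) == dinuc_counts(seq)
    assert Counter(out) == Counter(seq)


# ---------------------------------------------------------------------------
# motif insertion activity
# ---------------------------------------------------------------------------


def test_activity_is_mean_influence_and_order_invariant(tiny_results):
    rng = np.random.default_rng(0)
    peaks = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(6)]
    pwm = make_pwm("GATAAGGA", 1.0)
    act = motif_activity(tiny_results, pwm, peaks, n_background=5, seed=2)
    assert act.activity.shape == (1, 5)
    assert np.allclose(act.activity[0], act.influence[0].mean(axis=0))
    # averaging commutes with background order
    perm = rng.permutation(5)
    assert np.allclose(act.influence[0][perm].mean(axis=0), act.activity[0])


def test_inserting_motif_already_present_gives_zero_influence(tiny_results):
    from probatac.tf_activity import _insert_consensus

    rng = np.random.default_rng(1)
    pwm = make_pwm("GATAAGGA", 1.0)
    background = _insert_consensus("".join(rng.choice(list("ACGT"), 30)), pwm)
    inserted = _insert_consensus(background, pwm)
    assert inserted == background          # identical input
    from probatac.sequence_io import one_hot_encode

    ys = tiny_results.predict(one_hot_encode([background, inserted]))
    assert np.allclose(ys[0] - ys[1], 0.0)


def test_activity_errors(tiny_results):
    pwm = make_pwm("GATAAGGA", 1.0)
    with pytest.raises(ValueError):
        motif_activity(tiny_results, pwm, ["ACGT" * 8], n_background=0, seed=0)
    wide = make_pwm("A" * 40, 1.0)
    with pytest.raises(ValueError):
        motif_activity(tiny_results, wide, ["ACGT" * 8], n_background=2, seed=0)


def test_activity_library_z_normalisation(tiny_results):
    rng = np.random.default_rng(3)
    peaks = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(4)]
    lib = [make_pwm("GATAAGGA", 1.0), make_pwm("CACGTGAC", 1.0)]
    act = activity_library(tiny_results, lib, peaks, n_background=4, seed=0)
    z = act.normalized()
    assert z.shape == act.activity.shape
    assert np.allclose(z.mean(axis=1), 0.0, atol=1e-12)


def test_activity_logit_scale_and_instance_sampling(tiny_results):
    rng = np.random.default_rng(6)
    peaks = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(4)]
    pwm = make_pwm("GATAAGGA", 0.8)
    prob = motif_activity(tiny_results, pwm, peaks, n_background=4, seed=1)
    logit = motif_activity(tiny_results, pwm, peaks, n_background=4, seed=1,
                           scale="logit")
    assert prob.activity.shape == logit.activity.shape
    assert not np.allclose(prob.activity, logit.activity)
    sampled = motif_activity(tiny_results, pwm, peaks, n_background=4, seed=1,
                             sample_instances=3)
    again = motif_activity(tiny_results, pwm, peaks, n_background=4, seed=1,
                           sample_instances=3)
    assert np.array_equal(sampled.activity, again.activity)


# ---------------------------------------------------------------------------
# in-silico saturation mutagenesis
# ---------------------------------------------------------------------------


def test_ism_scores_sum_to_zero_per_position(tiny_results):
    rng = np.random.default_rng(2)
    seq = "".join(rng.choice(list("ACGT"), 30))
    res = ism(tiny_results, seq)
    assert res.scores.shape == (30, 4, 5)
    assert np.allclose(res.scores.sum(axis=1), 0.0, atol=1e-9)


def test_ism_reference_score_is_scaled_sum_of_alternative_deltas(tiny_results):
    """Centring over the four bases (raw reference delta = 0) forces the
    reference's normalized score to -(sum of the three raw alternative
    deltas)/4, and makes the centring idempotent."""
    rng = np.random.default_rng(4)
    seq = "".join(rng.choice(list("ACGT"), 30))
    res = ism(tiny_results, seq)
    alphabet = "ACGT"
    for p in (0, 13, 29):
        ref = alphabet.index(seq[p])
        alts = [b for b in range(4) if b != ref]
        raw_alt = res.scores[p, alts] - res.scores[p, ref]  # undo the centring
        assert np.allclose(res.scores[p, ref], -raw_alt.sum(axis=0) / 4.0,
                           atol=1e-9)
        centred_again = res.scores[p] - res.scores[p].mean(axis=0)
        assert np.allclose(centred_again, res.scores[p], atol=1e-12)


def test_ism_constant_predictor_gives_zero_scores(tiny_results):
    import copy

    frozen = copy.deepcopy(tiny_results)
    frozen._net.params["pred_w"].data[:] = 0.0
    frozen._net.params["pred_b"].data[:] = 0.0
    seq = "ACGT" * 7 + "AC"
    res = ism(frozen, seq)
    assert np.allclose(res.scores, 0.0)


def test_ism_length_mismatch(tiny_results):
    with pytest.raises(ValueError):
        ism(tiny_results, "ACGT")


def test_pwm_ism_score_reductions(tiny_results):
    rng = np.random.default_rng(5)
    seq = "".join(rng.choice(list("ACGT"), 30))
    res = ism(tiny_results, seq)
    zeros = res.scores * 0.0
    from probatac.tf_activity import ISMResult

    z = ISMResult(zeros, seq)
    pwm = make_pwm("GATA", 1.0)
    assert np.allclose(pwm_ism_score(z, pwm, 0), 0.0)
    # one-hot PWM picks out exactly the consensus-base ISM entries
    onehot = make_pwm("GATA", 1.0)
    expected = sum(res.scores[3 + i, "ACGT".index(b)]
                   for i, b in enumerate("GATA"))
    assert np.allclose(pwm_ism_score(res, onehot, 3), expected, atol=1e-12)
    # uniform PWM hits the per-position zero-sum invariant
    uniform = make_pwm("GATA", 0.25)
    assert np.allclose(pwm_ism_score(res, uniform, 3), 0.0, atol=1e-9)
    with pytest.raises(ValueError):
        pwm_ism_score(res, pwm, 28)
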