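"""Shared heavyweight fixtures built lazily and cached in-process."""

import functools

import spinereg as sr
from spinereg.curvature import compute_curvature
from spinereg.matcher import EncoderConfig, SALayerConfig, small_training_config, train
from spinereg.sampling import equalize_density


def tiny_encoder_config() -> EncoderConfig:
    return EncoderConfig(
        sa_layers=(SALayerConfig(48, 6.0, (8, 16)), SALayerConfig(24, 12.0, (16, 16)),
                   SALayerConfig(8, 24.0, (16, 16))),
        fp_mlp_widths=(16,), feature_dim=16, attention_heads=2, attention_blocks=1,
        group_size=8, points_per_cloud=256)


@functools.lru_cache(maxsize=1)
def tiny_model_and_pair():
    """A briefly trained tiny matcher plus one curvature-bearing test pair."""
    pairs = [sr.make_pair(sr.PairSpec(seed=60 + i, n_preop=3000, overlap_target=0.04))
             for i in range(3)]
    triples = sr.training_triples_from_pairs(pairs, seed=0)
    model = train(triples, tiny_encoder_config(), small_training_config(epochs=4))
    pair = sr.make_pair(sr.PairSpec(seed=77, n_preop=3000, overlap_target=0.04))
    intra_eq = equalize_density(pair.intraop, pair.preop)
    preop_c = compute_curvature(pair.preop)
    intraop_c = compute_curvature(intra_eq)
    return model, pair, preop_c, intraop_c
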