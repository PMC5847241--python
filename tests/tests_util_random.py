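"""Shared helpers for generating small random test instances."""


def random_corpus(rng, n_max=5, len_max=8, n_min=2, len_min=3):
    n = int(rng.integers(n_min, n_max + 1))
    return ["".join("ACGU"[b] for b in rng.integers(0, 4, int(rng.integers(len_min, len_max + 1))))
            for _ in range(n)]


def random_dna(rng, length):
    return "".join("ACGT"[b] for b in rng.integers(0, 4, length))


def random_rna(rng, length):
    return "".join("ACGU"[b] for b in rng.integers(0, 4, length))
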