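"""Independent naive re-implementation of the chain dynamics.

Deliberately written with plain nested Python loops and no shared code with
the package's vectorized forward pass; serves as the oracle in equivalence
tests.
"""

import math


def naive_activation(name, s):
    if name == "tanh":
        return math.tanh(s)
    if name == "logistic":
        return 1.0 / (1.0 + math.exp(-s))
    if name == "identity":
        return s
    raise ValueError(name)


def naive_forward(phi, omega, radius, iterations, activation, output_mode, type_indices):
    """Evaluate the iterated cell dynamics position by position.

    ``phi`` is a list of M internal weights, ``omega`` a list of M lists of
    length 2*radius+1, ``type_indices`` the residue types of the peptide.
    States start at zero; out-of-chain neighbors contribute zero.
    """
    L = len(type_indices)
    x = [0.0] * L
    for _ in range(iterations):
        new_x = []
        for i in range(L):
            a = type_indices[i]
            s = phi[a]
            for j in range(-radius, radius + 1):
                k = i + j
                if 0 <= k < L:
                    s += omega[a][j + radius] * x[k]
            new_x.append(naive_activation(activation, s))
        x = new_x
    total = sum(x)
    return total if output_mode == "sum" else total / L
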