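"""Numba-compiled mass-action vector field for the nine-species scheme.

The species order is fixed everywhere in the package:

    0:E  1:S  2:ES  3:EP  4:P  5:I  6:PI  7:EPI  8:PIE

(E = TF:VIIa, S = X, P = Xa, I = TFPI; colon complexes as named).  The rate
vector ``K`` holds the fifteen constants in the order

    k+1, k-1, k+2, k+3, k-3, k+4, k-4, k+5, k-5, k+6, k-6, k+7, k-7, k+8, k-8

Flow enters only through the substrate/product/inhibitor exchange terms
``k_flow*(S_up - S)``, ``-k_flow*P``, ``k_flow*(I_up - I)`` and
``-k_flow*PI``; the enzyme species are wall-bound and untouched by flow.
With ``k_flow = 0`` the flow field is bitwise identical to the static one,
so a single code path serves both models.
"""

from __future__ import annotations

import numpy as np
from numba import njit

N_SPECIES = 9
SPECIES = ("E", "S", "ES", "EP", "P", "I", "PI", "EPI", "PIE")

RATE_ORDER = (
    "k_plus_1", "k_minus_1", "k_plus_2", "k_plus_3", "k_minus_3",
    "k_plus_4", "k_minus_4", "k_plus_5", "k_minus_5", "k_plus_6",
    "k_minus_6", "k_plus_7", "k_minus_7", "k_plus_8", "k_minus_8",
)


@njit(cache=True)
def rhs(y, t, K, k_flow, S_up, I_up):
    E, S, ES, EP, P, I, PI, EPI, PIE = y
    k1 = K[0]; km1 = K[1]; k2 = K[2]; k3 = K[3]; km3 = K[4]
    k4 = K[5]; km4 = K[6]; k5 = K[7]; km5 = K[8]; k6 = K[9]
    km6 = K[10]; k7 = K[11]; km7 = K[12]; k8 = K[13]; km8 = K[14]

    r1 = k1 * E * S - km1 * ES      # E + S <-> E:S
    r2 = k2 * ES                    # E:S -> E:P (catalysis)
    r3 = k3 * E * P - km3 * EP      # E + P <-> E:P (product rebinding)
    r4 = k4 * P * I - km4 * PI      # P + I <-> P:I (solution inhibition)
    r5 = k5 * E * PI - km5 * PIE    # E + P:I <-> P:I:E (nullified by default)
    r6 = k6 * EP * I - km6 * EPI    # E:P + I <-> E:P:I (direct binding)
    r7 = k7 * EPI - km7 * PIE       # E:P:I <-> P:I:E (conformational lock)
    r8 = k8 * E * PI - km8 * EPI    # E + P:I <-> E:P:I (indirect binding)

    out = np.empty(9)
    out[0] = -r1 - r3 - r5 - r8
    out[1] = -r1 + k_flow * (S_up - S)
    out[2] = r1 - r2
    out[3] = r2 + r3 - r6
    out[4] = -r3 - r4 - k_flow * P
    out[5] = -r4 - r6 + k_flow * (I_up - I)
    out[6] = r4 - r5 - r8 - k_flow * PI
    out[7] = r6 - r7 + r8
    out[8] = r5 + r7
    return out


@njit(cache=True)
def jac(y, t, K, k_flow, S_up, I_up):
    E, S, ES, EP, P, I, PI, EPI, PIE = y
    k1 = K[0]; km1 = K[1]; k2 = K[2]; k3 = K[3]; km3 = K[4]
    k4 = K[5]; km4 = K[6]; k5 = K[7]; km5 = K[8]; k6 = K[9]
    km6 = K[10]; k7 = K[11]; km7 = K[12]; k8 = K[13]; km8 = K[14]

    J = np.zeros((9, 9))
    # r1 = k1*E*S - km1*ES affects E(-), S(-), ES(+)
    a = k1 * S; b = k1 * E
    J[0, 0] -= a; J[0, 1] -= b; J[0, 2] += km1
    J[1, 0] -= a; J[1, 1] -= b; J[1, 2] += km1
    J[2, 0] += a; J[2, 1] += b; J[2, 2] -= km1
    # r2 = k2*ES affects ES(-), EP(+)
    J[2, 2] -= k2
    J[3, 2] += k2
    # r3 = k3*E*P - km3*EP affects E(-), P(-), EP(+)
    c = k3 * P; d = k3 * E
    J[0, 0] -= c; J[0, 4] -= d; J[0, 3] += km3
    J[4, 0] -= c; J[4, 4] -= d; J[4, 3] += km3
    J[3, 0] += c; J[3, 4] += d; J[3, 3] -= km3
    # r4 = k4*P*I - km4*PI affects P(-), I(-), PI(+)
    e = k4 * I; f = k4 * P
    J[4, 4] -= e; J[4, 5] -= f; J[4, 6] += km4
    J[5, 4] -= e; J[5, 5] -= f; J[5, 6] += km4
    J[6, 4] += e; J[6, 5] += f; J[6, 6] -= km4
    # r5 = k5*E*PI - km5*PIE affects E(-), PI(-), PIE(+)
    g = k5 * PI; h = k5 * E
    J[0, 0] -= g; J[0, 6] -= h; J[0, 8] += km5
    J[6, 0] -= g; J[6, 6] -= h; J[6, 8] += km5
    J[8, 0] += g; J[8, 6] += h; J[8, 8] -= km5
    # r6 = k6*EP*I - km6*EPI affects EP(-), I(-), EPI(+)
    m = k6 * I; n = k6 * EP
    J[3, 3] -= m; J[3, 5] -= n; J[3, 7] += km6
    J[5, 3] -= m; J[5, 5] -= n; J[5, 7] += km6
    J[7, 3] += m; J[7, 5] += n; J[7, 7] -= km6
    # r7 = k7*EPI - km7*PIE affects EPI(-), PIE(+)
    J[7, 7] -= k7; J[7, 8] += km7
    J[8, 7] += k7; J[8, 8] -= km7
    # r8 = k8*E*PI - km8*EPI affects E(-), PI(-), EPI(+)
    p = k8 * PI; q = k8 * E
    J[0, 0] -= p; J[0, 6] -= q; J[0, 7] += km8
    J[6, 0] -= p; J[6, 6] -= q; J[6, 7] += km8
    J[7, 0] += p; J[7, 6] += q; J[7, 7] -= km8
    # flow exchange terms on S, P, I, PI
    J[1, 1] -= k_flow
    J[4, 4] -= k_flow
    J[5, 5] -= k_flow
    J[6, 6] -= k_flow
    return J


@njit(cache=True)
def preincubation_rhs(y, t, k4, km4, P0, I0):
    """Scalar ODE for the Xa:TFPI complex during pre-incubation.

    Only reaction 4 runs (no enzyme present); P and I follow from the
    moiety totals P0 and I0, leaving d[PI]/dt = k4*(P0-PI)*(I0-PI) - km4*PI.
    """
    PI = y[0]
    out = np.empty(1)
    out[0] = k4 * (P0 - PI) * (I0 - PI) - km4 * PI
    return out
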