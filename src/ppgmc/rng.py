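"""Counter-based pseudorandom numbers with per-photon streams.

Every photon owns an independent SplitMix64 stream whose initial state is a
hash of ``(run_seed, photon_index)``.  Because a photon's draws depend only on
its own stream, the batched transport kernel and the one-photon-at-a-time
reference loop consume *identical* random numbers for photon ``i`` no matter
how photons are scheduled.  This is what makes the engine-vs-reference
equivalence check well defined.

Draw order within one photon's life (the stream contract):

1. launch: ``xi_radius``, ``xi_azimuth``
2. per transport step in tissue: ``xi_step``
3. per interface encounter (layer/layer, tissue/gap, gap/tissue):
   ``xi_fresnel`` — always drawn, even when the reflectance is 0 or 1
4. per interaction site: ``xi_costheta``, ``xi_azimuth``
5. after an interaction, if the weight is below the roulette threshold:
   ``xi_roulette``

Gap flights, sensor-face mirror bounces and detection tests draw nothing.

This module is the pure-Python implementation used by the reference loop;
:mod:`ppgmc._kernel` carries a bit-identical ``uint64`` twin for numba.  A
unit test pins the two streams against each other.
"""

from __future__ import annotations

_MASK = 0xFFFFFFFFFFFFFFFF
_GAMMA = 0x9E3779B97F4A7C15
_STREAM_SALT = 0xD1B54A32D192ED03


def mix64(z: int) -> int:
    """SplitMix64 finalizer (Stafford variant 13)."""
    z &= _MASK
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK
    return (z ^ (z >> 31)) & _MASK


def photon_stream_state(seed: int, photon_index: int) -> int:
    """Initial SplitMix64 state for photon ``photon_index`` of run ``seed``."""
    a = mix64(((seed & _MASK) + 1) * _GAMMA)
    b = mix64(((photon_index & _MASK) + 1) * _STREAM_SALT)
    return (a ^ b) & _MASK


def next_uniform(state: int) -> tuple[float, int]:
    """Advance the stream; return ``(u, new_state)`` with ``0 < u < 1``.

    The top 53 bits of the mixed output form the mantissa, so ``u`` is a
    multiple of 2**-53 strictly below 1; an exact zero is bumped to 2**-53
    because step sampling needs ``ln(u)`` finite.
    """
    state = (state + _GAMMA) & _MASK
    u = (mix64(state) >> 11) * 2.0**-53
    if u == 0.0:
        u = 2.0**-53
    return u, state


class PhotonStream:
    """Convenience wrapper around one photon's uniform stream."""

    __slots__ = ("state",)

    def __init__(self, seed: int, photon_index: int):
        self.state = photon_stream_state(seed, photon_index)

    def uniform(self) -> float:
        u, self.state = next_uniform(self.state)
        return u
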