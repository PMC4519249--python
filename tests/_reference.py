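"""Independent reference implementations used as oracles in the tests.

These deliberately share no code with the package: the traffic oracle is a
fixed-step time-stepping simulation (rather than event-driven), and the ODE
oracles are term-by-term transcriptions of the mass balances.  They are only
meant for tiny, noiseless, probability-degenerate configurations where both
implementations must agree exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass
class RefRound:
    origin: str
    index: int
    fate: str
    truncated_length: int | None = None


def brute_force_traffic(config, dt: float = 1e-3):
    """Fixed-step oracle for noiseless, deterministic-outcome configurations.

    Requires noise_cv = 0, v_sd = 0, sdc_survival in {0, 1},
    collision_one_survives = 0 and pause removal probabilities in {0, 1}.
    Returns a list of RefRound in (promoter, index) order.
    """
    assert config.pX.noise_cv == 0 and config.pY.noise_cv == 0
    assert config.v_sd == 0
    assert config.sdc_survival in (0.0, 1.0)
    assert config.collision_one_survives == 0.0
    for ps in config.pause_sites:
        assert ps.removal_prob_on_hit in (0.0, 1.0)

    L, v = config.L, config.v_mean
    half = config.fp_ec / 2.0
    delta = config.delta_critical

    stronger = "pX" if config.pX.tau_B <= config.pY.tau_B else "pY"
    horizon = config.n_rounds * getattr(config, stronger).tau_B

    def schedule(prom):
        p = getattr(config, prom)
        n = config.n_rounds if prom == stronger else int(horizon // p.tau_B)
        return [((i + 1) * p.tau_B, (i + 1) * p.tau_B + p.tau_I)
                for i in range(n)]

    sched = {"pX": schedule("pX"), "pY": schedule("pY")}
    fates = {prom: [None] * len(sched[prom]) for prom in ("pX", "pY")}
    pauses = {"pX": {ps.position: ps for ps in config.pause_sites
                     if ps.strand == "sense"},
              "pY": {ps.position: ps for ps in config.pause_sites
                     if ps.strand == "antisense"}}

    class EC:
        def __init__(self, prom, idx):
            self.prom, self.idx = prom, idx
            self.pos = 1.0 if prom == "pX" else float(L)
            self.dir = 1.0 if prom == "pX" else -1.0
            self.pause_left = 0.0
            self.seen_pauses = set()
            self.done_pos = (L + 70 + half) if prom == "pX" else (1 - 70 - half)

        def step(self):
            if self.pause_left > 0:
                self.pause_left = max(0.0, self.pause_left - dt)
                return
            new = self.pos + self.dir * v * dt
            # entering a pause site stops the clock for its duration
            for pos, ps in pauses[self.prom].items():
                if pos in self.seen_pauses:
                    continue
                if (self.pos - pos) * (new - pos) <= 0 and self.pos != new:
                    self.seen_pauses.add(pos)
                    self.pause_left = ps.duration
                    new = float(pos)
                    break
            self.pos = new

        @property
        def paused(self):
            return self.pause_left > 0

        def length_at(self, pos):
            if self.prom == "pX":
                return int(math.floor(pos))
            return int(math.floor(L - pos + 1))

    occl = {"pY": (L - half, L + 70 + half), "pX": (1 + half, -70 - half)}
    sdi_pos = {"pY": L - half, "pX": 1 + half}

    ecs: list[EC] = []
    ics: dict[str, tuple[int, float, float]] = {}  # prom -> (idx, bind, fire)
    next_round = {"pX": 0, "pY": 0}
    t = 0.0
    t_end = horizon + (L + 160) / v + sum(ps.duration
                                          for ps in config.pause_sites) + 5.0

    def opposing(prom):
        return [e for e in ecs if e.prom != prom]

    while t <= t_end:
        t += dt
        # binding attempts
        for prom in ("pX", "pY"):
            j = next_round[prom]
            if j < len(sched[prom]) and sched[prom][j][0] <= t:
                bind, fire = sched[prom][j]
                lo, hi = sorted(occl[prom])
                if any(lo < e.pos < hi for e in opposing(prom)):
                    fates[prom][j] = RefRound(prom, j, "occluded")
                else:
                    ics[prom] = (j, bind, fire)
                next_round[prom] += 1
        # firing
        for prom in ("pX", "pY"):
            if prom in ics and ics[prom][2] <= t:
                j = ics.pop(prom)[0]
                fates[prom][j] = RefRound(prom, j, "full_length")
                ecs.append(EC(prom, j))
        # movement
        old_pos = {id(e): e.pos for e in ecs}
        for e in ecs:
            e.step()
        # sitting-duck encounters (EC front crosses the promoter boundary)
        for prom in ("pX", "pY"):
            if prom not in ics:
                continue
            j, bind, fire = ics[prom]
            bpos = sdi_pos[prom]
            for e in opposing(prom):
                crossed = (old_pos[id(e)] - bpos) * (e.pos - bpos) < 0 \
                    or e.pos == bpos
                if crossed:
                    if config.sdc_survival == 1.0:
                        fates[e.prom][e.idx] = RefRound(
                            e.prom, e.idx, "truncated",
                            e.length_at(bpos))
                        ecs.remove(e)
                    else:
                        fates[prom][j] = RefRound(prom, j, "sdi_dislodged")
                        del ics[prom]
                    break
        # collisions inside the overlap
        removed = set()
        for es in [e for e in ecs if e.prom == "pX"]:
            for ea in [e for e in ecs if e.prom == "pY"]:
                if id(es) in removed or id(ea) in removed:
                    continue
                if not (1 <= es.pos <= L and 1 <= ea.pos <= L):
                    continue
                if ea.pos - es.pos <= delta:
                    if es.paused != ea.paused:
                        paused, mover = (es, ea) if es.paused else (ea, es)
                        prob = pauses[paused.prom][int(round(paused.pos))] \
                            .removal_prob_on_hit
                        victim = paused if prob == 1.0 else mover
                        fates[victim.prom][victim.idx] = RefRound(
                            victim.prom, victim.idx, "truncated",
                            victim.length_at(victim.pos))
                        removed.add(id(victim))
                    else:  # both fall (collision_one_survives = 0)
                        for e in (es, ea):
                            fates[e.prom][e.idx] = RefRound(
                                e.prom, e.idx, "truncated",
                                e.length_at(e.pos))
                            removed.add(id(e))
        ecs = [e for e in ecs if id(e) not in removed
               and (e.pos - e.done_pos) * e.dir < 0]

    out = []
    for prom in ("pX", "pY"):
        for j, r in enumerate(fates[prom]):
            out.append(r if r is not None else RefRound(prom, j, "full_length"))
    return out


# ---------------------------------------------------------------------------
# double-entry ODE right-hand sides
# ---------------------------------------------------------------------------

def rna_rhs_reference(state, k, kin):
    """Term-by-term transcription of the eight RNA mass balances.

    ``k`` is a dict with production rates kx, ky, kxk, kyh.
    """
    x, y, xk, yh, xy, xky, xyh, xkyh = state
    dx = (k["kx"] - kin.k_bxy * x * y - kin.k_bxyh * x * yh
          + kin.k_uxy * (xy + xyh) - (kin.mu + kin.lambda_x) * x)
    dy = (k["ky"] - kin.k_bxy * y * x - kin.k_bxky * y * xk
          + kin.k_uxy * (xy + xky) - (kin.mu + kin.lambda_y) * y)
    dxk = (k["kxk"] - kin.k_bxky * xk * y - kin.k_bxkyh * xk * yh
           + kin.k_uxy * xky + kin.k_uxkyh * xkyh
           - (kin.mu + kin.lambda_xk) * xk)
    dyh = (k["kyh"] - kin.k_bxyh * x * yh - kin.k_bxkyh * xk * yh
           + kin.k_uxy * xyh + kin.k_uxkyh * xkyh
           - (kin.mu + kin.lambda_yh) * yh)
    dxy = kin.k_bxy * x * y - (kin.k_uxy + kin.mu + kin.lambda_xy) * xy
    dxky = kin.k_bxky * xk * y - (kin.k_uxy + kin.mu + kin.lambda_xky) * xky
    dxyh = kin.k_bxyh * x * yh - (kin.k_uxy + kin.mu + kin.lambda_xyh) * xyh
    dxkyh = (kin.k_bxkyh * xk * yh
             - (kin.k_uxkyh + kin.mu + kin.lambda_xkyh) * xkyh)
    return [dx, dy, dxk, dyh, dxy, dxky, dxyh, dxkyh]


def protein_rhs_reference(rna, prot, k, kin, p):
    """Term-by-term transcription of the four protein mass balances."""
    x, y = rna[0], rna[1]
    X, Y, Z, XZ = prot
    dX = p.k_X * x - p.k_XZ * X * Z + p.k_uXZ * XZ - (p.mu + p.lambda_X) * X
    dY = p.k_Y * y - (p.mu + p.lambda_Y) * Y
    dZ = (p.k_WZ + p.k_YZ * Y - p.k_XZ * X * Z + p.k_uXZ * XZ
          - (p.mu + p.lambda_Z) * Z)
    dXZ = p.k_XZ * X * Z - (p.k_uXZ + p.mu + p.lambda_XZ) * XZ
    return [dX, dY, dZ, dXZ]
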