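"""Abstract SIMT resource model: occupancy, block counts, and tile sizing.

A purely arithmetic model of a SIMT accelerator, used by the batch planner to
decide how many subject sequences to process per round.  No hardware is
probed: the model is a handful of integers — streaming multiprocessor count
``SM_num``, maximum resident threads per SM ``T_max``, hardware block cap per
SM ``B_hw``, and warp size — plus optional register/shared-memory/user block
limits.

Occupancy is the fraction of resident-thread capacity in use,

    occupancy = (B * T_num) / T_max,       B = min(B_user, B_reg, B_shr, B_hw)

and the adaptive tile size for a workload of N permutations per subject is

    T = floor(SM_num * T_max / N)

so that T subjects * N permutations saturates the modeled device each round.
The default profile (14 SMs, 1024 resident threads, 8 blocks, warp 32) is a
Tesla C2050-class device.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

UNCONSTRAINED = None


class InfeasibleTileError(ValueError):
    """Tile size came out zero: N exceeds the device's resident-thread budget."""


@dataclass(frozen=True)
class DeviceModel:
    name: str = "tesla-c2050"
    sm_num: int = 14
    t_max: int = 1024
    b_hw: int = 8
    warp_size: int = 32
    b_reg: Optional[int] = UNCONSTRAINED
    b_shr: Optional[int] = UNCONSTRAINED
    b_user: Optional[int] = UNCONSTRAINED

    def __post_init__(self):
        for field_name in ("sm_num", "t_max", "b_hw", "warp_size"):
            if getattr(self, field_name) < 1:
                raise ValueError(f"{field_name} must be >= 1")
        for field_name in ("b_reg", "b_shr", "b_user"):
            v = getattr(self, field_name)
            if v is not None and v < 1:
                raise ValueError(f"{field_name} must be >= 1 or unconstrained")


#: Named device profiles usable from the CLI.
DEVICE_PROFILES = {
    "tesla-c2050": DeviceModel(),
}


def occupancy(blocks_per_sm: int, threads_per_block: int, t_max: int) -> float:
    """Occupancy = (B * T_num) / T_max for one streaming multiprocessor."""
    if blocks_per_sm < 1 or threads_per_block < 1 or t_max < 1:
        raise ValueError("occupancy inputs must be positive")
    return (blocks_per_sm * threads_per_block) / t_max


def occupancy_bound(device: DeviceModel, threads_per_block: int) -> float:
    """Upper bound (B_hw * T_num) / T_max, independent of the workload."""
    return (device.b_hw * threads_per_block) / device.t_max


def workload_blocks(total_threads: int, threads_per_block: int) -> int:
    """Total blocks needed for a workload: ceil(total_threads / T_num)."""
    if total_threads < 1 or threads_per_block < 1:
        raise ValueError("workload inputs must be positive")
    return math.ceil(total_threads / threads_per_block)


def check_warp_multiple(device: DeviceModel, threads_per_block: int) -> bool:
    """Warn (and return False) when T_num is not a multiple of the warp size."""
    if threads_per_block % device.warp_size != 0:
        warnings.warn(
            f"threads per block ({threads_per_block}) is not a multiple of the "
            f"warp size ({device.warp_size}); under-populated warps waste lanes",
            stacklevel=2,
        )
        return False
    return True


def effective_blocks(
    device: DeviceModel,
    threads_per_block: int,
    total_blocks: Optional[int] = None,
) -> int:
    """Active blocks per SM: min of all configured limits and the workload.

    The resident-thread budget allows ceil(T_max / T_num) blocks; the
    hardware allows B_hw; register/shared-memory/user limits apply when
    configured; and when ``total_blocks`` is given, no SM can hold more than
    its share ceil(total_blocks / SM_num) of the workload.
    """
    if threads_per_block < 1:
        raise ValueError("threads per block must be positive")
    limits = [math.ceil(device.t_max / threads_per_block), device.b_hw]
    for limit in (device.b_reg, device.b_shr, device.b_user):
        if limit is not None:
            limits.append(limit)
    if total_blocks is not None:
        if total_blocks < 0:
            raise ValueError("total_blocks must be >= 0")
        limits.append(math.ceil(total_blocks / device.sm_num))
    return min(limits)


def distribute_blocks(total_blocks: int, sm_num: int) -> list[int]:
    """Round-robin assignment of blocks to SMs (descending counts)."""
    base, extra = divmod(total_blocks, sm_num)
    return [base + 1] * extra + [base] * (sm_num - extra)


def tile_size(device: DeviceModel, n_permutations: int) -> int:
    """Subjects per round: T = floor(SM_num * T_max / N).

    Raises :class:`InfeasibleTileError` when T would be 0, i.e. one
    subject's N permutations already exceed the device's resident-thread
    budget; reduce N or chunk permutations.
    """
    if n_permutations < 1:
        raise ValueError("number of permutations must be >= 1")
    t = (device.sm_num * device.t_max) // n_permutations
    if t == 0:
        raise InfeasibleTileError(
            f"N={n_permutations} exceeds SM_num*T_max="
            f"{device.sm_num * device.t_max}; tile size would be 0 — "
            f"use a smaller N or chunk the permutations"
        )
    return t


@dataclass(frozen=True)
class TilePlan:
    """Planner output for one batching configuration."""

    tile: int
    threads_per_block: int
    total_blocks: int
    blocks_per_sm: int
    occupancy: float
    alignments_per_round: int


def plan(
    device: DeviceModel,
    n_permutations: int,
    threads_per_block: int = 64,
) -> TilePlan:
    """Full tile plan: tile size, block counts, occupancy for one round.

    One round performs tile * N alignments (one thread each in the modeled
    execution), so the per-SM workload is tile * N / SM_num threads.
    """
    check_warp_multiple(device, threads_per_block)
    t = tile_size(device, n_permutations)
    alignments = t * n_permutations
    total = workload_blocks(alignments, threads_per_block)
    b = effective_blocks(device, threads_per_block, total)
    occ = occupancy(b, threads_per_block, device.t_max)
    return TilePlan(
        tile=t,
        threads_per_block=threads_per_block,
        total_blocks=total,
        blocks_per_sm=b,
        occupancy=occ,
        alignments_per_round=alignments,
    )
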