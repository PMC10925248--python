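"""Session orchestrator: source -> pipeline -> calibration -> sinks.

Frames are grabbed into a bounded FIFO buffer and processed by a pool of
worker threads; results are re-ordered by frame_number before being emitted,
so the output is identical regardless of worker count or completion order.
Every grabbed frame yields exactly one output row; frames dropped at the
buffer (realtime mode) or failing inside the pipeline yield flagged rows.
"""

from __future__ import annotations

import logging
import os
import threading
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from vogkit.core.buffer import FrameBuffer
from vogkit.core.types import EyeDatum, Frame, Quality, dropped_datum

log = logging.getLogger("vogkit.session")


@dataclass
class SessionReport:
    frames_grabbed: int = 0
    frames_processed: int = 0
    frames_dropped: int = 0
    pipeline_errors: int = 0
    source_error: Optional[str] = None
    output_paths: list = field(default_factory=list)

    def check_conservation(self) -> bool:
        return self.frames_grabbed == self.frames_processed + self.frames_dropped


def default_worker_count(max_workers: int = 8) -> int:
    return max(1, min(os.cpu_count() or 1, max_workers))


def run_session(
    source: Iterable[Frame],
    pipeline,
    calibration=None,
    sinks: Sequence = (),
    *,
    n_workers: Optional[int] = None,
    buffer_capacity: int = 64,
    realtime: bool = False,
) -> SessionReport:
    """Run one tracking session to completion.

    Parameters
    ----------
    source : iterable of Frame
        Already pre-processed per-eye frames (see ``video_io.preprocess``).
    pipeline : object
        Must provide ``process(frame) -> EyeDatum``.  If it provides
        ``process_for_reference(frame)`` it is called once with the first
        frame, before any worker starts, so stateful references (e.g. the
        torsion reference profile) are set deterministically.
    calibration : object, optional
        If given, ``apply_to_datum(datum)`` is called on each row in order.
    sinks : sequence
        Objects with ``write(datum)``; ``close()`` is called at session end.
    realtime : bool
        If True, a full buffer drops the incoming frame (flagged row);
        otherwise the grabber waits for space, so no frames are dropped and
        output is deterministic.
    """
    if n_workers is None or n_workers < 1:
        n_workers = default_worker_count()

    buffer = FrameBuffer(buffer_capacity)
    report = SessionReport()

    results: dict[int, EyeDatum] = {}
    results_lock = threading.Lock()
    results_ready = threading.Condition(results_lock)
    grab_order: deque[int] = deque()  # frame numbers in grabbed order
    grab_done = threading.Event()

    def put_result(datum: EyeDatum) -> None:
        with results_ready:
            results[datum.frame_number] = datum
            results_ready.notify_all()

    source_iter = iter(source)

    # First frame primes stateful pipelines (reference profiles) before any
    # worker runs, keeping multi-worker output deterministic.
    try:
        first_frame = next(source_iter)
    except StopIteration:
        first_frame = None
    except Exception as exc:  # noqa: BLE001 - source failure -> clean shutdown
        report.source_error = str(exc)
        first_frame = None

    if first_frame is not None and hasattr(pipeline, "process_for_reference"):
        try:
            pipeline.process_for_reference(first_frame)
        except Exception:  # noqa: BLE001
            log.exception("process_for_reference failed; continuing")

    def grab() -> None:
        def handle(frame: Frame) -> None:
            report.frames_grabbed += 1
            with results_ready:
                grab_order.append(frame.frame_number)
            if realtime:
                status = buffer.enqueue(frame)
                if status == "dropped":
                    report.frames_dropped += 1
                    put_result(
                        dropped_datum(frame.frame_number, frame.timestamp, frame.eye)
                    )
            else:
                buffer.enqueue_blocking(frame)

        try:
            if first_frame is not None:
                handle(first_frame)
            for frame in source_iter:
                handle(frame)
        except Exception as exc:  # noqa: BLE001
            report.source_error = str(exc)
            log.error("source error: %s", exc)
        finally:
            grab_done.set()
            buffer.close()
            with results_ready:
                results_ready.notify_all()

    def work() -> None:
        while True:
            frame = buffer.dequeue()
            if frame is None:
                return
            try:
                datum = pipeline.process(frame)
            except Exception as exc:  # noqa: BLE001 - plugin errors never abort
                log.error("pipeline error on frame %d: %s", frame.frame_number, exc)
                report.pipeline_errors += 1
                datum = EyeDatum(
                    frame.frame_number, frame.timestamp, frame.eye,
                    quality=Quality.ERROR,
                )
            put_result(datum)

    grab_thread = threading.Thread(target=grab, name="vogkit-grab", daemon=True)
    workers = [
        threading.Thread(target=work, name=f"vogkit-worker-{i}", daemon=True)
        for i in range(n_workers)
    ]
    grab_thread.start()
    for w in workers:
        w.start()

    # In-order emission: the head of the grabbed-order queue is the next
    # frame to emit; wait until its result has been produced.
    while True:
        with results_ready:
            datum = None
            while True:
                if grab_order and grab_order[0] in results:
                    datum = results.pop(grab_order.popleft())
                    break
                if grab_done.is_set() and not grab_order:
                    break
                results_ready.wait(timeout=0.05)
        if datum is None:
            break
        if datum.quality is not Quality.DROPPED:
            report.frames_processed += 1
        if calibration is not None and hasattr(calibration, "apply_to_datum"):
            calibration.apply_to_datum(datum)
        for sink in sinks:
            sink.write(datum)

    grab_thread.join()
    for w in workers:
        w.join()
    for sink in sinks:
        if hasattr(sink, "close"):
            sink.close()
        if hasattr(sink, "path"):
            report.output_paths.append(str(sink.path))
    return report
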