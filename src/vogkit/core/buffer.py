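"""Bounded FIFO buffer between frame grabbing and image processing.

When the buffer is full the *incoming* frame is rejected (counted as a
drop); queued frames are never evicted, preserving temporal continuity of
the processed stream.
"""

from __future__ import annotations

import threading
from collections import deque
from typing import Optional


class FrameBuffer:
    """Thread-safe FIFO holding at most ``capacity`` frames."""

    def __init__(self, capacity: int):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = capacity
        self._queue: deque = deque()
        self._lock = threading.Lock()
        self._not_empty = threading.Condition(self._lock)
        self._not_full = threading.Condition(self._lock)
        self._closed = False
        self.dropped = 0

    def __len__(self) -> int:
        with self._lock:
            return len(self._queue)

    def enqueue(self, frame) -> str:
        """Try to append; returns "accepted" or "dropped" (buffer full)."""
        with self._lock:
            if len(self._queue) >= self.capacity:
                self.dropped += 1
                return "dropped"
            self._queue.append(frame)
            self._not_empty.notify()
            return "accepted"

    def enqueue_blocking(self, frame) -> str:
        """Append, waiting for space (offline mode: backpressure, no drops)."""
        with self._lock:
            while len(self._queue) >= self.capacity and not self._closed:
                self._not_full.wait()
            if self._closed:
                raise RuntimeError("buffer closed")
            self._queue.append(frame)
            self._not_empty.notify()
            return "accepted"

    def dequeue(self, timeout: Optional[float] = None):
        """Pop the oldest frame; returns None once closed and empty."""
        with self._lock:
            while not self._queue:
                if self._closed:
                    return None
                if not self._not_empty.wait(timeout=timeout):
                    return None
            frame = self._queue.popleft()
            self._not_full.notify()
            return frame

    def close(self) -> None:
        with self._lock:
            self._closed = True
            self._not_empty.notify_all()
            self._not_full.notify_all()
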