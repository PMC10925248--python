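"""Minimal remote-control protocol for driving sessions from other programs.

Wire format: one JSON object per line over TCP.  Requests carry a ``verb``,
optional ``args`` and an ``id``; every request is answered exactly once
with a response echoing the id and a ``status`` of "ok" or "error".

Verbs: status, startRecording, stopRecording, setSetting, getLastSample,
recordEvent.
"""

from __future__ import annotations

import dataclasses
import json
import socketserver
import threading
from typing import Optional

from vogkit.core.settings import LIVE_SETTINGS, TrackerSettings
from vogkit.core.types import EyeDatum
from vogkit.recording import DataFileWriter, datum_to_row

VERBS = {
    "status", "startRecording", "stopRecording",
    "setSetting", "getLastSample", "recordEvent",
}


class SessionController:
    """Shared state between a running session and the remote interface."""

    def __init__(self, settings: Optional[TrackerSettings] = None):
        self.settings = settings if settings is not None else TrackerSettings()
        self._lock = threading.Lock()
        self.state = "idle"  # idle | running
        self.last_datum: Optional[EyeDatum] = None
        self.frames_seen = 0
        self._recorder: Optional[DataFileWriter] = None
        self.recording_path: Optional[str] = None

    # --- called by the processing loop -------------------------------
    def ingest(self, datum: EyeDatum) -> None:
        with self._lock:
            self.state = "running"
            self.last_datum = datum
            self.frames_seen += 1
            if self._recorder is not None:
                self._recorder.write(datum)

    def finish(self) -> None:
        with self._lock:
            self.state = "idle"
            if self._recorder is not None:
                self._recorder.close()
                self._recorder = None

    # --- remote-facing operations ------------------------------------
    def status(self) -> dict:
        with self._lock:
            return {
                "state": self.state,
                "frames_seen": self.frames_seen,
                "recording": self._recorder is not None,
            }

    def start_recording(self, path: str) -> None:
        with self._lock:
            if self._recorder is not None:
                return  # idempotent
            self._recorder = DataFileWriter(
                path, settings_hash=self.settings.content_hash()
            )
            self.recording_path = path

    def stop_recording(self) -> None:
        with self._lock:
            if self._recorder is None:
                return  # idempotent no-op
            self._recorder.close()
            self._recorder = None

    def set_setting(self, key: str, value) -> None:
        bare = key.split(".")[-1]
        if bare not in LIVE_SETTINGS:
            raise ValueError(
                f"setting '{key}' is not live-adjustable; "
                f"live settings: {', '.join(sorted(LIVE_SETTINGS))}"
            )
        dotted = key if "." in key else f"pipeline.{key}"
        self.settings.set_value(dotted, value)
        with self._lock:
            if self._recorder is not None:
                fn = self.last_datum.frame_number if self.last_datum else -1
                self._recorder.write_event(
                    self.last_datum.timestamp if self.last_datum else 0.0,
                    f"setSetting {dotted}={value}", frame_number=fn,
                )

    def get_last_sample(self) -> Optional[dict]:
        with self._lock:
            if self.last_datum is None:
                return None
            return dataclasses.asdict(datum_to_row(self.last_datum))

    def record_event(self, label: str) -> None:
        with self._lock:
            if self._recorder is None:
                raise ValueError("not recording; cannot append event marker")
            t = self.last_datum.timestamp if self.last_datum else 0.0
            fn = self.last_datum.frame_number if self.last_datum else -1
            self._recorder.write_event(t, label, frame_number=fn)


def handle_command(controller: SessionController, request: dict) -> dict:
    """Dispatch one request; always returns a response with the request id."""
    rid = request.get("id")
    verb = request.get("verb")
    args = request.get("args", {}) or {}

    def ok(**payload) -> dict:
        return {"id": rid, "status": "ok", **payload}

    def err(message: str) -> dict:
        return {"id": rid, "status": "error", "error": message}

    if verb not in VERBS:
        return err(f"unknown verb {verb!r}; known: {', '.join(sorted(VERBS))}")
    try:
        if verb == "status":
            return ok(**controller.status())
        if verb == "startRecording":
            path = args.get("path")
            if not path:
                return err("startRecording requires args.path")
            controller.start_recording(path)
            return ok()
        if verb == "stopRecording":
            controller.stop_recording()
            return ok()
        if verb == "setSetting":
            if "key" not in args or "value" not in args:
                return err("setSetting requires args.key and args.value")
            controller.set_setting(args["key"], args["value"])
            return ok()
        if verb == "getLastSample":
            return ok(sample=controller.get_last_sample())
        if verb == "recordEvent":
            controller.record_event(args.get("label", ""))
            return ok()
    except Exception as exc:  # noqa: BLE001 - protocol errors never crash
        return err(str(exc))
    return err("unhandled verb")  # pragma: no cover


class _Handler(socketserver.StreamRequestHandler):
    def handle(self) -> None:
        for raw in self.rfile:
            raw = raw.strip()
            if not raw:
                continue
            try:
                request = json.loads(raw)
            except json.JSONDecodeError as exc:
                response = {"id": None, "status": "error",
                            "error": f"bad JSON: {exc}"}
            else:
                response = handle_command(self.server.controller, request)
            self.wfile.write((json.dumps(response) + "\n").encode())
            self.wfile.flush()


class RemoteServer(socketserver.ThreadingTCPServer):
    """JSON-lines TCP server; one request per line, one response each."""

    allow_reuse_address = True
    daemon_threads = True

    def __init__(self, controller: SessionController,
                 host: str = "127.0.0.1", port: int = 0):
        super().__init__((host, port), _Handler)
        self.controller = controller

    @property
    def address(self):
        return self.socket.getsockname()

    def serve_in_background(self) -> threading.Thread:
        thread = threading.Thread(target=self.serve_forever, daemon=True)
        thread.start()
        return thread
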