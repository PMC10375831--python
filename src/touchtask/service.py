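"""Read-only status API over a running (or finished) session.

The behavioural engine and any monitoring consumer are deliberately
decoupled: the engine only ever *pushes* partial trial logs into a
shared :class:`SessionStatus` buffer via its observer hook, and the
HTTP consumer *pulls* snapshots from that buffer. Killing, detaching or
never starting the consumer therefore cannot perturb the session — a
property the test suite checks by diffing paired runs.

Endpoints (JSON over HTTP, stdlib server):

* ``/snapshot``  — live counts / engagement (zero counts when idle)
* ``/protocol``  — protocol name and parameter snapshot
* ``/metadata``  — session identifiers
"""

from __future__ import annotations

import json
import threading
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from typing import Optional

from .core import ProtocolConfig, TrialRecord
from .runner import snapshot


class SessionStatus:
    """Thread-safe buffer the engine's observer hook writes into."""

    def __init__(self) -> None:
        self._lock = threading.Lock()
        self._trials: list[TrialRecord] = []
        self._elapsed = 0.0
        self.session_id: Optional[str] = None
        self.animal_id: Optional[str] = None
        self.protocol_name: Optional[str] = None
        self.protocol_params: dict = {}

    def attach(self, session_id: str, animal_id: str,
               protocol_name: str, cfg: ProtocolConfig) -> None:
        with self._lock:
            self.session_id = session_id
            self.animal_id = animal_id
            self.protocol_name = protocol_name
            self.protocol_params = cfg.model_dump(mode="json")

    def observer(self, trials: list[TrialRecord], elapsed: float) -> None:
        """Engine-facing callback (matches run_session's observer signature)."""
        with self._lock:
            self._trials = trials
            self._elapsed = elapsed

    def snapshot_payload(self) -> dict:
        with self._lock:
            snap = snapshot(self._trials, self._elapsed)
            return {"active": self.session_id is not None,
                    **snap.model_dump()}

    def protocol_payload(self) -> dict:
        with self._lock:
            return {"name": self.protocol_name, "params": self.protocol_params}

    def metadata_payload(self) -> dict:
        with self._lock:
            return {"session_id": self.session_id, "animal_id": self.animal_id}


class _Handler(BaseHTTPRequestHandler):
    status: SessionStatus  # injected by StatusServer

    def log_message(self, *args) -> None:  # silence request logging
        pass

    def do_GET(self) -> None:
        routes = {
            "/snapshot": self.status.snapshot_payload,
            "/protocol": self.status.protocol_payload,
            "/metadata": self.status.metadata_payload,
        }
        fn = routes.get(self.path)
        if fn is None:
            self.send_response(404)
            self.end_headers()
            return
        body = json.dumps(fn()).encode()
        self.send_response(200)
        self.send_header("Content-Type", "application/json")
        self.send_header("Content-Length", str(len(body)))
        self.end_headers()
        self.wfile.write(body)


class StatusServer:
    """Local HTTP status surface; ``port=0`` picks a free port."""

    def __init__(self, status: SessionStatus, host: str = "127.0.0.1", port: int = 0):
        self.status = status
        handler = type("BoundHandler", (_Handler,), {"status": status})
        self._server = ThreadingHTTPServer((host, port), handler)
        self._thread = threading.Thread(target=self._server.serve_forever, daemon=True)

    @property
    def port(self) -> int:
        return self._server.server_address[1]

    @property
    def url(self) -> str:
        host, port = self._server.server_address[:2]
        return f"http://{host}:{port}"

    def start(self) -> "StatusServer":
        self._thread.start()
        return self

    def close(self) -> None:
        self._server.shutdown()
        self._server.server_close()

    def __enter__(self) -> "StatusServer":
        return self.start()

    def __exit__(self, *exc) -> None:
        self.close()


def status_api(status: Optional[SessionStatus] = None, port: int = 0) -> StatusServer:
    """Create (unstarted) a status server over the given buffer."""
    return StatusServer(status or SessionStatus(), port=port)
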