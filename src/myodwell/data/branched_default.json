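{
 "name": "branched",
 "notes": "Reconstruction of the six-state branched topology: the uni-cycle (cycle F) plus leading-head ADP release ED->EE (rate adp_release_trail/gating_g), the enzymatic closure through DE (trailing release DE->EE, ADP rebinding EE->ED, EE->DE, DE->DD; cycle E), and load-driven slip steps EE->EE at site offsets +/-1 (cycle M). A second leading-head release DD->DE and a futile-hydrolysis TD->DD are available as builder toggles but excluded here: an ATP-independent leak out of DD broadens the saturating-ATP dwell distribution even without gating, contrary to the known agreement between the four- and six-state descriptions at high [ATP].",
 "states": [
  "DD",
  "ED",
  "TD",
  "DT",
  "DE",
  "EE"
 ],
 "transitions": [
  {
   "from": "DD",
   "to": "ED",
   "rate": "adp_release_trail",
   "law": {
    "type": "release",
    "species": "ADP"
   },
   "offset": 0,
   "cycles": [
    "F"
   ]
  },
  {
   "from": "ED",
   "to": "DD",
   "rate": "adp_bind",
   "law": {
    "type": "binding",
    "species": "ADP"
   },
   "offset": 0,
   "cycles": [
    "F"
   ]
  },
  {
   "from": "ED",
   "to": "TD",
   "rate": "atp_bind",
   "law": {
    "type": "binding",
    "species": "ATP"
   },
   "offset": 0,
   "cycles": [
    "F"
   ]
  },
  {
   "from": "TD",
   "to": "ED",
   "rate": "atp_dissoc",
   "law": {
    "type": "release",
    "species": "ATP"
   },
   "offset": 0,
   "cycles": [
    "F"
   ]
  },
  {
   "from": "TD",
   "to": "DT",
   "rate": "step_fwd",
   "law": {
    "type": "mechanical",
    "direction": "forward"
   },
   "offset": 1,
   "cycles": [
    "F"
   ]
  },
  {
   "from": "DT",
   "to": "TD",
   "rate": "step_bwd",
   "law": {
    "type": "mechanical",
    "direction": "backward"
   },
   "offset": -1,
   "cycles": [
    "F"
   ]
  },
  {
   "from": "DT",
   "to": "DD",
   "rate": "p_release",
   "law": {
    "type": "release",
    "species": "P"
   },
   "offset": 0,
   "cycles": [
    "F"
   ]
  },
  {
   "from": "DD",
   "to": "DT",
   "rate": "p_bind",
   "law": {
    "type": "binding",
    "species": "P"
   },
   "offset": 0,
   "cycles": [
    "F"
   ]
  },
  {
   "from": "ED",
   "to": "EE",
   "rate": "adp_release_lead",
   "law": {
    "type": "release",
    "species": "ADP"
   },
   "offset": 0,
   "cycles": [
    "E"
   ]
  },
  {
   "from": "DE",
   "to": "EE",
   "rate": "adp_release_trail",
   "law": {
    "type": "release",
    "species": "ADP"
   },
   "offset": 0,
   "cycles": [
    "E"
   ]
  },
  {
   "from": "EE",
   "to": "ED",
   "rate": "adp_bind",
   "law": {
    "type": "binding",
    "species": "ADP"
   },
   "offset": 0,
   "cycles": [
    "E"
   ]
  },
  {
   "from": "EE",
   "to": "DE",
   "rate": "adp_bind",
   "law": {
    "type": "binding",
    "species": "ADP"
   },
   "offset": 0,
   "cycles": [
    "E"
   ]
  },
  {
   "from": "DE",
   "to": "DD",
   "rate": "adp_bind",
   "law": {
    "type": "binding",
    "species": "ADP"
   },
   "offset": 0,
   "cycles": [
    "E"
   ]
  },
  {
   "from": "EE",
   "to": "EE",
   "rate": "slip_fwd",
   "law": {
    "type": "mechanical",
    "direction": "forward"
   },
   "offset": 1,
   "cycles": [
    "M"
   ]
  },
  {
   "from": "EE",
   "to": "EE",
   "rate": "slip_bwd",
   "law": {
    "type": "mechanical",
    "direction": "backward"
   },
   "offset": -1,
   "cycles": [
    "M"
   ]
  }
 ]
}
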