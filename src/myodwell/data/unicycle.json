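{
 "name": "unicycle",
 "notes": "Four-state chemomechanical cycle F: trailing-head ADP release DD->ED, ATP binding ED->TD, forward step TD->DT (site offset +1), hydrolysis/P release DT->DD; reverse transitions carry zero default rates except the backstep DT->TD (offset -1).",
 "states": [
  "DD",
  "ED",
  "TD",
  "DT"
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
  }
 ]
}
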