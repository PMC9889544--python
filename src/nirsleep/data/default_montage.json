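{
 "homotopic_offset": 26,
 "optodes": [
  {
   "id": 1,
   "kind": "source",
   "position": [
    0.28,
    0.9
   ],
   "occipital": false
  },
  {
   "id": 2,
   "kind": "source",
   "position": [
    0.13,
    0.72
   ],
   "occipital": false
  },
  {
   "id": 3,
   "kind": "source",
   "position": [
    0.33,
    0.72
   ],
   "occipital": false
  },
  {
   "id": 4,
   "kind": "source",
   "position": [
    0.28,
    0.54
   ],
   "occipital": false
  },
  {
   "id": 5,
   "kind": "source",
   "position": [
    0.13,
    0.36
   ],
   "occipital": false
  },
  {
   "id": 6,
   "kind": "source",
   "position": [
    0.33,
    0.36
   ],
   "occipital": false
  },
  {
   "id": 7,
   "kind": "source",
   "position": [
    0.28,
    0.2
   ],
   "occipital": false
  },
  {
   "id": 8,
   "kind": "source",
   "position": [
    0.24,
    0.07
   ],
   "occipital": true
  },
  {
   "id": 9,
   "kind": "source",
   "position": [
    0.72,
    0.9
   ],
   "occipital": false
  },
  {
   "id": 10,
   "kind": "source",
   "position": [
    0.87,
    0.72
   ],
   "occipital": false
  },
  {
   "id": 11,
   "kind": "source",
   "position": [
    0.67,
    0.72
   ],
   "occipital": false
  },
  {
   "id": 12,
   "kind": "source",
   "position": [
    0.72,
    0.54
   ],
   "occipital": false
  },
  {
   "id": 13,
   "kind": "source",
   "position": [
    0.87,
    0.36
   ],
   "occipital": false
  },
  {
   "id": 14,
   "kind": "source",
   "position": [
    0.67,
    0.36
   ],
   "occipital": false
  },
  {
   "id": 15,
   "kind": "source",
   "position": [
    0.72,
    0.2
   ],
   "occipital": false
  },
  {
   "id": 16,
   "kind": "source",
   "position": [
    0.76,
    0.07
   ],
   "occipital": true
  },
  {
   "id": 1,
   "kind": "detector",
   "position": [
    0.18,
    0.9
   ],
   "occipital": false
  },
  {
   "id": 2,
   "kind": "detector",
   "position": [
    0.38,
    0.9
   ],
   "occipital": false
  },
  {
   "id": 3,
   "kind": "detector",
   "position": [
    0.23,
    0.72
   ],
   "occipital": false
  },
  {
   "id": 4,
   "kind": "detector",
   "position": [
    0.43,
    0.72
   ],
   "occipital": false
  },
  {
   "id": 5,
   "kind": "detector",
   "position": [
    0.18,
    0.54
   ],
   "occipital": false
  },
  {
   "id": 6,
   "kind": "detector",
   "position": [
    0.38,
    0.54
   ],
   "occipital": false
  },
  {
   "id": 7,
   "kind": "detector",
   "position": [
    0.23,
    0.36
   ],
   "occipital": false
  },
  {
   "id": 8,
   "kind": "detector",
   "position": [
    0.43,
    0.36
   ],
   "occipital": false
  },
  {
   "id": 9,
   "kind": "detector",
   "position": [
    0.18,
    0.2
   ],
   "occipital": false
  },
  {
   "id": 10,
   "kind": "detector",
   "position": [
    0.16,
    0.07
   ],
   "occipital": true
  },
  {
   "id": 11,
   "kind": "detector",
   "position": [
    0.32,
    0.07
   ],
   "occipital": true
  },
  {
   "id": 12,
   "kind": "detector",
   "position": [
    0.42,
    0.07
   ],
   "occipital": true
  },
  {
   "id": 13,
   "kind": "detector",
   "position": [
    0.82,
    0.9
   ],
   "occipital": false
  },
  {
   "id": 14,
   "kind": "detector",
   "position": [
    0.62,
    0.9
   ],
   "occipital": false
  },
  {
   "id": 15,
   "kind": "detector",
   "position": [
    0.77,
    0.72
   ],
   "occipital": false
  },
  {
   "id": 16,
   "kind": "detector",
   "position": [
    0.57,
    0.72
   ],
   "occipital": false
  },
  {
   "id": 17,
   "kind": "detector",
   "position": [
    0.82,
    0.54
   ],
   "occipital": false
  },
  {
   "id": 18,
   "kind": "detector",
   "position": [
    0.62,
    0.54
   ],
   "occipital": false
  },
  {
   "id": 19,
   "kind": "detector",
   "position": [
    0.77,
    0.36
   ],
   "occipital": false
  },
  {
   "id": 20,
   "kind": "detector",
   "position": [
    0.57,
    0.36
   ],
   "occipital": false
  },
  {
   "id": 21,
   "kind": "detector",
   "position": [
    0.82,
    0.2
   ],
   "occipital": false
  },
  {
   "id": 22,
   "kind": "detector",
   "position": [
    0.78,
    0.16
   ],
   "occipital": false
  },
  {
   "id": 23,
   "kind": "detector",
   "position": [
    0.68,
    0.07
   ],
   "occipital": true
  },
  {
   "id": 24,
   "kind": "detector",
   "position": [
    0.58,
    0.07
   ],
   "occipital": true
  }
 ],
 "channels": [
  {
   "id": 1,
   "source": 1,
   "detector": 1
  },
  {
   "id": 2,
   "source": 1,
   "detector": 2
  },
  {
   "id": 3,
   "source": 2,
   "detector": 1
  },
  {
   "id": 4,
   "source": 2,
   "detector": 3
  },
  {
   "id": 5,
   "source": 1,
   "detector": 3
  },
  {
   "id": 6,
   "source": 3,
   "detector": 2
  },
  {
   "id": 7,
   "source": 3,
   "detector": 3
  },
  {
   "id": 8,
   "source": 3,
   "detector": 4
  },
  {
   "id": 9,
   "source": 2,
   "detector": 5
  },
  {
   "id": 10,
   "source": 4,
   "detector": 3
  },
  {
   "id": 11,
   "source": 4,
   "detector": 5
  },
  {
   "id": 12,
   "source": 4,
   "detector": 6
  },
  {
   "id": 13,
   "source": 3,
   "detector": 6
  },
  {
   "id": 14,
   "source": 5,
   "detector": 5
  },
  {
   "id": 15,
   "source": 5,
   "detector": 7
  },
  {
   "id": 16,
   "source": 4,
   "detector": 7
  },
  {
   "id": 17,
   "source": 6,
   "detector": 6
  },
  {
   "id": 18,
   "source": 6,
   "detector": 7
  },
  {
   "id": 19,
   "source": 6,
   "detector": 8
  },
  {
   "id": 20,
   "source": 5,
   "detector": 9
  },
  {
   "id": 21,
   "source": 7,
   "detector": 7
  },
  {
   "id": 22,
   "source": 7,
   "detector": 9
  },
  {
   "id": 23,
   "source": 4,
   "detector": 4
  },
  {
   "id": 24,
   "source": 8,
   "detector": 10
  },
  {
   "id": 25,
   "source": 8,
   "detector": 11
  },
  {
   "id": 26,
   "source": 7,
   "detector": 12
  },
  {
   "id": 27,
   "source": 9,
   "detector": 13
  },
  {
   "id": 28,
   "source": 9,
   "detector": 14
  },
  {
   "id": 29,
   "source": 10,
   "detector": 13
  },
  {
   "id": 30,
   "source": 10,
   "detector": 15
  },
  {
   "id": 31,
   "source": 9,
   "detector": 15
  },
  {
   "id": 32,
   "source": 11,
   "detector": 14
  },
  {
   "id": 33,
   "source": 11,
   "detector": 15
  },
  {
   "id": 34,
   "source": 11,
   "detector": 16
  },
  {
   "id": 35,
   "source": 10,
   "detector": 17
  },
  {
   "id": 36,
   "source": 12,
   "detector": 15
  },
  {
   "id": 37,
   "source": 12,
   "detector": 17
  },
  {
   "id": 38,
   "source": 12,
   "detector": 18
  },
  {
   "id": 39,
   "source": 11,
   "detector": 18
  },
  {
   "id": 40,
   "source": 13,
   "detector": 17
  },
  {
   "id": 41,
   "source": 13,
   "detector": 19
  },
  {
   "id": 42,
   "source": 12,
   "detector": 19
  },
  {
   "id": 43,
   "source": 14,
   "detector": 18
  },
  {
   "id": 44,
   "source": 14,
   "detector": 19
  },
  {
   "id": 45,
   "source": 14,
   "detector": 20
  },
  {
   "id": 46,
   "source": 13,
   "detector": 21
  },
  {
   "id": 47,
   "source": 15,
   "detector": 19
  },
  {
   "id": 48,
   "source": 15,
   "detector": 22
  },
  {
   "id": 49,
   "source": 12,
   "detector": 16
  },
  {
   "id": 50,
   "source": 16,
   "detector": 22
  },
  {
   "id": 51,
   "source": 16,
   "detector": 23
  },
  {
   "id": 52,
   "source": 15,
   "detector": 24
  }
 ]
}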