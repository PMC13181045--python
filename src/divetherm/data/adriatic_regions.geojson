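{
 "type": "FeatureCollection",
 "features": [
  {
   "type": "Feature",
   "properties": {
    "name": "WACC"
   },
   "geometry": {
    "type": "Polygon",
    "coordinates": [
     [
      [
       12.5894,
       45.1156
      ],
      [
       13.7891,
       43.7812
      ],
      [
       14.1836,
       43.1429
      ],
      [
       14.7092,
       42.6611
      ],
      [
       15.5859,
       42.3381
      ],
      [
       16.2289,
       42.1894
      ],
      [
       16.8663,
       41.9997
      ],
      [
       18.1711,
       40.9527
      ],
      [
       18.7564,
       40.3057
      ],
      [
       18.7997,
       40.137
      ],
      [
       18.742,
       39.9727
      ],
      [
       18.6557,
       39.8936
      ],
      [
       18.5457,
       39.8535
      ],
      [
       18.4287,
       39.8586
      ],
      [
       18.3227,
       39.908
      ],
      [
       17.7464,
       40.5281
      ],
      [
       16.5581,
       41.4777
      ],
      [
       15.3963,
       41.7685
      ],
      [
       14.3697,
       42.1602
      ],
      [
       13.7277,
       42.7485
      ],
      [
       13.3098,
       43.4179
      ],
      [
       12.7296,
       44.0465
      ],
      [
       12.2195,
       44.6579
      ],
      [
       12.1517,
       44.8184
      ],
      [
       12.1844,
       44.9894
      ],
      [
       12.2579,
       45.0805
      ],
      [
       12.3608,
       45.1364
      ],
      [
       12.4772,
       45.1488
      ],
      [
       12.5894,
       45.1156
      ]
     ]
    ]
   }
  },
  {
   "type": "Feature",
   "properties": {
    "name": "NA"
   },
   "geometry": {
    "type": "Polygon",
    "coordinates": [
     [
      [
       12.0,
       43.3
      ],
      [
       16.2,
       43.3
      ],
      [
       16.2,
       45.95
      ],
      [
       12.0,
       45.95
      ],
      [
       12.0,
       43.3
      ]
     ]
    ]
   }
  },
  {
   "type": "Feature",
   "properties": {
    "name": "MA"
   },
   "geometry": {
    "type": "Polygon",
    "coordinates": [
     [
      [
       12.0,
       41.9
      ],
      [
       18.2,
       41.9
      ],
      [
       18.2,
       43.3
      ],
      [
       12.0,
       43.3
      ],
      [
       12.0,
       41.9
      ]
     ]
    ]
   }
  },
  {
   "type": "Feature",
   "properties": {
    "name": "SA"
   },
   "geometry": {
    "type": "Polygon",
    "coordinates": [
     [
      [
       14.8,
       40.05
      ],
      [
       18.55,
       40.05
      ],
      [
       19.9,
       40.05
      ],
      [
       19.9,
       41.9
      ],
      [
       14.8,
       41.9
      ],
      [
       14.8,
       40.05
      ]
     ]
    ]
   }
  }
 ]
}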