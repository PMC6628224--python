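state,region,site_id,n_logs,longitude,latitude,n_clade_a,n_clade_b
Alabama,Little River Canyon Nature Preserve,A134,1,-85.58357,34.45540,3,0
Alabama,Bankhead NF,A130,1,-87.38140,34.29811,1,5
Alabama,Bankhead NF,C10,1,-87.39905,34.28235,0,1
Alabama,Bankhead NF,A133,1,-87.27680,34.17659,6,1
Alabama,Bankhead NF,C13,1,-87.32465,34.10336,1,0
Alabama,Bankhead NF,C15,1,-87.32407,34.10230,1,0
Alabama,Bankhead NF,C16,1,-87.32454,34.10151,1,0
Alabama,Shinbone Ridge Road,A138,1,-85.84679,34.14676,0,2
Alabama,Talladega NF,A137,2,-85.45730,33.96340,7,2
Alabama,Talladega NF,A41,1,-85.49764,33.91858,2,0
Alabama,Talladega NF,A12,1,-85.69391,33.57157,2,0
Alabama,Talladega NF,A13,1,-85.70074,33.56059,6,0
Alabama,Talladega NF,A117,1,-85.80658,33.47105,4,2
Alabama,Talladega NF,A124,1,-85.87318,33.40451,7,0
Alabama,Talladega NF,A15,2,-85.88391,33.39762,7,2
Alabama,Talladega NF,A126,1,-85.93017,33.36136,5,0
Georgia,W-Chattahoochee NF,A18,1,-84.71137,34.87866,0,1
Georgia,W-Chattahoochee NF,A154,1,-84.69117,34.75933,3,0
Georgia,Johns Mtn WMA,A04,1,-85.06536,34.57297,1,0
Georgia,Johns Mtn WMA,A153,1,-85.06541,34.57281,1,0
Georgia,Johns Mtn WMA,A152,1,-85.07185,34.56806,1,0
Georgia,Johns Mtn WMA,A10,1,-85.24043,34.56416,2,3
Georgia,Red Top Mtn SP,A140,1,-84.71650,34.15014,1,1
Georgia,Oconee NF,A150,2,-83.29258,33.72088,4,0
Mississippi,Tishomingo SP,A86,2,-88.19299,34.60502,2,3
Mississippi,Holly Springs NF,M01,1,-89.44006,34.50676,1,0
Mississippi,Holly Springs NF,M05,1,-89.44013,34.50665,1,0
Mississippi,UMFS,FS03,1,-89.38657,34.42800,3,0
Mississippi,UMFS,M14,1,-89.38293,34.42396,2,0
Mississippi,Whirlpool Trail,M13,1,-89.55107,34.34670,3,0
Mississippi,Tombigbee SP,M-5,3,-88.61667,34.23167,2,1
Mississippi,County Road 484,M-4,4,-89.33333,33.83333,2,2
Mississippi,Malmaison State WMA,M-6,1,-90.04333,33.68667,1,0
Mississippi,Natchez Trace Pkwy,M-3,4,-89.16667,33.52833,0,4
Mississippi,Noxubee NWR,M-1,9,-88.77833,33.29167,5,4
Mississippi,Tombigbee NF,M-2,7,-89.07500,33.20667,0,7
North Carolina,Great Smoky Mtn NP,A156,1,-83.30981,35.52144,3,0
North Carolina,Nantahala NF,A92,1,-83.59187,35.32969,14,0
Tennessee,Great Smoky Mtn NP,A159,1,-83.52245,35.66272,2,0
Tennessee,Rich Mtn. Loop Trail,T-1,3,-83.79833,35.61667,2,1
Tennessee,Natchez Trace Pkwy,A73,1,-87.52677,35.39384,1,2
Virginia,Tuleyries Lane,V-2,6,-78.07500,39.06167,6,0
Virginia,Shenandoah River SP,V-1,4,-78.31000,38.84167,3,1
Virginia,Jefferson NF,A53,1,-79.80718,37.40599,2,0
West Virginia,Cacapon Resort SP,V-3,2,-78.27667,39.59000,2,0
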