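year,discount_rate_pct,usd_per_t
2021,2.5,2000
2022,2.5,2100
2023,2.5,2100
2024,2.5,2200
2025,2.5,2200
2026,2.5,2300
2027,2.5,2300
2028,2.5,2400
2029,2.5,2400
2030,2.5,2500
2031,2.5,2600
2032,2.5,2600
2033,2.5,2700
2034,2.5,2700
2035,2.5,2800
2036,2.5,2900
2037,2.5,2900
2038,2.5,3000
2039,2.5,3000
2040,2.5,3100
2041,2.5,3200
2042,2.5,3300
2043,2.5,3300
2044,2.5,3400
2045,2.5,3500
2046,2.5,3600
2047,2.5,3600
2048,2.5,3700
2049,2.5,3700
2050,2.5,3800
2021,3,1500
2022,3,1600
2023,3,1600
2024,3,1700
2025,3,1700
2026,3,1800
2027,3,1800
2028,3,1900
2029,3,1900
2030,3,2000
2031,3,2000
2032,3,2100
2033,3,2100
2034,3,2100
2035,3,2200
2036,3,2300
2037,3,2300
2038,3,2400
2039,3,2400
2040,3,2500
2041,3,2600
2042,3,2600
2043,3,2700
2044,3,2700
2045,3,2800
2046,3,2900
2047,3,2900
2048,3,3000
2049,3,3000
2050,3,3100
2021,5,700
2022,5,720
2023,5,750
2024,5,770
2025,5,800
2026,5,830
2027,5,860
2028,5,880
2029,5,910
2030,5,940
2031,5,970
2032,5,1000
2033,5,1040
2034,5,1070
2035,5,1100
2036,5,1140
2037,5,1180
2038,5,1220
2039,5,1260
2040,5,1300
2041,5,1340
2042,5,1380
2043,5,1420
2044,5,1460
2045,5,1500
2046,5,1540
2047,5,1580
2048,5,1620
2049,5,1660
2050,5,1700
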