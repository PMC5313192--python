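individual_id,sex,release_date,release_tl,recapture_date,recapture_tl
s1_000,female,2011-02-12,142.5,2014-03-30,146.0
s1_001,female,2007-10-19,138.5,2010-04-03,140.5
s1_002,female,2009-03-31,158.0,2012-11-07,159.5
s1_003,male,2009-12-12,126.5,2010-08-16,129.5
s1_004,female,2011-04-23,158.5,2012-08-21,161.0
s1_005,female,2008-02-26,164.5,2010-10-09,163.0
s1_006,female,2011-04-03,146.5,2014-02-11,144.0
s1_007,female,2007-11-12,147.0,2011-10-26,146.0
s1_008,female,2007-06-27,151.5,2009-04-22,149.0
s1_009,female,2010-01-21,126.5,2010-12-05,126.5
s1_010,female,2011-09-23,114.0,2012-11-15,109.5
s1_011,female,2008-09-22,131.5,2011-12-22,132.5
s1_012,male,2007-05-04,98.0,2009-01-14,101.0
s1_013,female,2010-02-19,140.5,2011-04-16,141.5
s1_014,female,2011-12-19,152.5,2013-11-06,159.0
s1_015,female,2008-11-01,114.0,2010-10-23,113.0
s1_016,female,2011-01-11,135.5,2011-09-13,138.0
s1_017,female,2007-11-09,146.0,2008-09-20,146.0
s1_018,male,2007-09-25,157.5,2011-07-04,156.0
s1_019,male,2008-05-14,147.5,2012-02-26,156.0
s1_020,male,2006-11-09,122.5,2008-04-01,128.0
s1_021,female,2014-02-16,163.5,2014-09-14,165.0
s1_022,female,2008-09-19,150.5,2011-02-13,150.0
s1_023,male,2010-05-15,137.0,2013-06-21,142.5
s1_024,female,2009-11-17,129.0,2012-12-13,128.5
s1_025,female,2008-12-07,165.0,2009-05-06,165.0
s1_026,male,2007-08-23,151.0,2009-11-23,156.5
s1_027,female,2007-12-17,137.5,2008-06-08,135.5
s1_028,female,2013-04-26,132.5,2014-08-27,135.5
s1_029,female,2008-03-30,127.5,2009-10-09,125.5
s1_030,male,2009-03-23,130.5,2011-09-13,135.0
s1_031,male,2008-06-17,156.5,2008-11-20,162.5
s1_032,female,2007-03-25,136.5,2011-07-01,142.5
s1_033,male,2010-03-15,144.5,2012-08-05,150.5
s1_034,female,2011-03-12,170.5,2012-09-30,169.5
s1_035,female,2010-02-11,143.5,2010-08-03,145.0
s1_036,female,2008-07-03,163.5,2009-08-27,164.0
s1_037,female,2008-12-21,133.5,2012-07-12,141.0
s1_038,female,2010-01-24,142.0,2012-04-05,142.5
s1_039,female,2008-09-20,175.5,2010-04-15,176.5
s1_040,male,2010-11-14,143.0,2012-09-14,149.0
s1_041,female,2011-02-02,137.5,2012-05-29,141.5
s1_042,female,2008-07-05,98.5,2012-06-19,114.0
s1_043,female,2011-12-06,110.5,2013-03-28,111.5
s1_044,female,2008-08-12,148.0,2010-01-31,146.0
s1_045,female,2008-04-13,121.0,2013-04-16,131.5
s1_046,female,2010-12-06,147.0,2011-05-05,146.5
s1_047,female,2010-01-24,138.5,2010-12-02,134.5
s1_048,female,2011-09-30,153.5,2012-03-27,148.5
s1_049,female,2013-03-05,150.0,2014-09-17,155.0
s1_050,female,2011-01-14,138.5,2011-09-21,142.5
s1_051,female,2011-05-03,132.5,2013-01-13,139.0
s1_052,female,2011-10-24,128.5,2013-12-25,129.0
s1_053,female,2009-11-08,157.0,2010-11-14,156.0
s1_054,female,2011-11-26,100.5,2013-11-23,104.0
s1_055,female,2008-04-05,111.0,2008-11-05,114.5
s1_056,female,2007-12-04,152.5,2012-10-29,157.0
s1_057,female,2011-03-25,148.5,2013-12-17,152.0
s1_058,female,2008-09-17,110.5,2011-06-03,114.0
s1_059,female,2008-07-02,112.5,2008-11-29,116.0
s1_060,female,2008-11-23,150.0,2011-08-04,150.5
s1_061,female,2007-10-28,148.5,2011-07-30,153.5
s1_062,male,2007-12-12,159.0,2010-12-22,161.5
s1_063,male,2009-07-27,130.5,2012-04-10,132.5
s1_064,female,2012-05-25,115.0,2013-06-20,112.5
s1_065,female,2008-10-12,138.0,2010-01-18,135.5
s1_066,female,2008-10-10,151.5,2013-08-04,157.5
s1_067,female,2010-01-17,132.5,2012-05-30,131.5
s1_068,female,2012-01-06,125.0,2014-06-05,125.5
s1_069,female,2006-12-03,136.0,2007-05-02,136.5
s1_070,female,2011-05-30,159.5,2012-10-31,158.0
s1_071,female,2010-04-17,145.5,2010-10-26,146.0
s1_072,male,2009-04-18,127.5,2010-07-23,124.5
s1_073,female,2008-08-27,154.5,2009-12-29,154.5
s1_074,female,2009-07-15,164.0,2010-01-08,167.0
s1_075,female,2007-05-18,164.5,2011-12-21,162.0
s1_076,female,2009-06-17,135.5,2014-08-30,141.0
s1_077,female,2007-04-01,169.5,2014-06-13,174.5
s1_078,female,2010-01-30,126.0,2013-01-04,129.0
s1_079,female,2011-01-19,168.5,2014-02-22,166.0
s1_080,female,2012-02-04,166.0,2013-07-17,164.0
s1_081,female,2013-07-27,162.0,2014-05-27,163.5
s1_082,male,2008-02-04,131.5,2012-11-13,140.5
s1_083,female,2007-03-14,142.5,2008-02-03,141.0
s1_084,female,2008-08-03,133.5,2013-10-27,146.0
s1_085,female,2009-06-07,142.5,2011-12-21,146.5
s1_086,female,2010-01-26,125.5,2013-05-26,128.0
s1_087,female,2011-07-31,164.0,2013-07-09,165.0
s1_088,female,2008-02-04,171.0,2008-11-19,167.0
s1_089,female,2006-12-01,148.0,2011-05-22,157.5
s1_090,female,2006-12-28,147.0,2009-03-27,146.5
s1_091,male,2010-12-16,125.5,2013-07-07,133.5
s1_092,female,2011-01-13,158.0,2011-11-24,159.5
s1_093,female,2011-01-28,167.5,2012-12-16,171.5
s1_094,female,2010-07-25,139.0,2013-12-11,149.0
s1_095,female,2010-03-04,130.5,2012-08-09,135.0
s1_096,female,2011-07-28,145.0,2014-06-07,155.0
s1_097,female,2006-10-19,122.0,2007-06-09,123.5
s1_098,female,2010-03-05,150.5,2011-12-01,150.5
s1_099,female,2007-05-20,180.0,2008-07-06,180.5
s1_100,female,2009-08-13,157.5,2013-03-15,161.0
s1_101,female,2007-02-14,146.0,2010-01-19,142.5
s1_102,female,2010-08-24,142.5,2014-02-02,148.5
s1_103,female,2012-04-24,143.0,2014-03-24,148.5
s1_104,female,2008-10-30,137.0,2012-10-15,140.5
s1_105,female,2007-06-26,127.5,2010-03-08,131.5
s1_106,female,2007-08-30,116.0,2012-03-16,132.5
s1_107,female,2010-01-30,151.0,2012-02-02,153.0
s1_108,female,2007-05-26,125.5,2008-05-11,127.5
s1_109,female,2009-11-08,142.5,2011-03-07,141.5
s1_110,female,2008-12-12,173.0,2010-03-28,177.5
s1_111,female,2006-12-15,144.0,2010-04-02,138.5
s1_112,male,2009-08-16,143.5,2011-10-23,139.0
s1_113,female,2007-03-25,161.0,2009-04-05,161.0
s1_114,female,2010-08-03,141.0,2013-09-20,145.0
s1_115,female,2010-08-13,145.0,2013-06-13,144.5
s1_116,male,2008-05-13,141.5,2009-04-11,142.0
s1_anchor,female,2007-07-01,103.0,2014-04-19,149.5
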